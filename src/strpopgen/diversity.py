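"""Genetic diversity statistics: allele frequencies, heterozygosity,
Hardy–Weinberg exact tests and maximum-likelihood silent-allele estimation.

The Hardy–Weinberg test is the conditional exact test: given the observed
allele counts at a locus, every way of pairing the allele copies into
diploid genotypes is equally likely under random union of gametes, and the
p-value is the probability of genotype arrays no more probable than the
observed one.  The conditional probability of a genotype count array
``{n_ij}`` with ``n`` individuals, allele counts ``{n_a}`` and ``h``
heterozygotes is

    P({n_ij} | {n_a}) = n! * prod_a n_a! * 2^h / ((2n)! * prod_{i<=j} n_ij!)

The null is sampled with a Markov chain on allele-copy arrangements whose
stationary distribution is uniform (random transpositions of two copies,
always accepted — a symmetric proposal targeting the uniform distribution),
which induces exactly the conditional distribution above on genotype
arrays.  Chain defaults are 10^6 steps after 10^6 dememorization
(burn-in) steps; tests and desk-scale runs use shorter chains.

Silent (null) alleles are estimated by an EM maximiser of the multinomial
class likelihood in which apparent homozygotes are a mixture of true
homozygotes (p_i^2) and visible/null heterozygotes (2 p_i r), and missing
calls are null/null (r^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .strdata import GenotypeTable, sort_alleles

__all__ = [
    "AlleleFrequencyTable",
    "LocusDiversity",
    "allele_frequencies",
    "heterozygosity",
    "HweResult",
    "hwe_exact_test",
    "hwe_direction",
    "bonferroni_threshold",
    "NullAlleleResult",
    "null_allele_ml",
    "diversity_table",
]


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-(population, locus) allele relative frequencies.

    ``freqs[(pop, locus)]`` maps allele label -> relative frequency;
    ``sample_sizes[(pop, locus)]`` is the number of gene copies counted
    (twice the non-missing individuals).  Cells with no data are absent
    from both maps and must be skipped downstream.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[str, float]]
    sample_sizes: dict[tuple[str, str], int]

    def frequency(self, pop: str, locus: str, allele: str) -> float:
        return self.freqs[(pop, locus)].get(allele, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pop, locus), f in self.freqs.items():
            for allele in sort_alleles(f):
                rows.append(
                    {"population": pop, "locus": locus, "allele": allele,
                     "frequency": f[allele],
                     "gene_copies": self.sample_sizes[(pop, locus)]}
                )
        return pd.DataFrame(rows)


def allele_frequencies(table: GenotypeTable, grouping: str = "phylum") -> AlleleFrequencyTable:
    """Count allele copies per (group, locus) and normalize.

    Missing and tri-allelic calls are excluded per locus (pairwise
    deletion).  With ``grouping='all'`` a single pooled population is used.
    """
    groups = _resolve_groups(table, grouping)
    freqs: dict[tuple[str, str], dict[str, float]] = {}
    sizes: dict[tuple[str, str], int] = {}
    for pop, rows in groups.items():
        for j, locus in enumerate(table.loci):
            counts: dict[str, int] = {}
            for i in rows:
                g = table.calls[i][j]
                if g.missing or g.triallelic:
                    continue
                for a in g.alleles:
                    counts[a] = counts.get(a, 0) + 1
            total = sum(counts.values())
            if total == 0:
                continue
            freqs[(pop, locus)] = {a: c / total for a, c in counts.items()}
            sizes[(pop, locus)] = total
    return AlleleFrequencyTable(list(groups), list(table.loci), freqs, sizes)


def _resolve_groups(table: GenotypeTable, grouping: str) -> dict[str, list[int]]:
    if grouping == "all":
        return {"all": list(range(table.n_individuals))}
    groups = table.group_indices(grouping)
    if not groups:
        raise ValueError(f"no individuals with known {grouping!r}")
    return groups


def _locus_genotypes(table: GenotypeTable, rows, locus_j: int):
    """Non-missing, diploid-only genotypes of a cell."""
    out = []
    for i in rows:
        g = table.calls[i][locus_j]
        if not g.missing and not g.triallelic:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity(table: GenotypeTable, grouping: str = "phylum") -> pd.DataFrame:
    """Observed and unbiased expected heterozygosity per (group, locus).

    Ho is the fraction of non-missing genotypes with two distinct alleles.
    He is the sample-size-corrected expected heterozygosity
    ``(2n / (2n - 1)) * (1 - sum p_hat^2)`` with 2n counted gene copies.
    Cells with fewer than two individuals get He = NaN (flagged undefined).
    """
    groups = _resolve_groups(table, grouping)
    rows_out = []
    for pop, rows in groups.items():
        for j, locus in enumerate(table.loci):
            gts = _locus_genotypes(table, rows, j)
            n = len(gts)
            if n == 0:
                continue
            ho = sum(g.heterozygous for g in gts) / n
            if n < 2:
                he = float("nan")
            else:
                counts: dict[str, int] = {}
                for g in gts:
                    for a in g.alleles:
                        counts[a] = counts.get(a, 0) + 1
                m = 2 * n
                p2 = sum((c / m) ** 2 for c in counts.values())
                he = (m / (m - 1)) * (1.0 - p2)
            rows_out.append({"population": pop, "locus": locus, "n": n,
                             "Ho": ho, "He": he})
    return pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# Hardy–Weinberg conditional exact test (Markov-chain Monte Carlo)
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    """Exact-test result with Monte-Carlo standard error."""

    p: float
    se: float
    steps: int
    applicable: bool = True
    note: str = ""


def _table_stats(pairs: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Genotype count matrix (upper triangular) and heterozygote count."""
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in pairs:
        i, j = (a, b) if a <= b else (b, a)
        counts[i, j] += 1
    het = int(pairs[:, 0].__ne__(pairs[:, 1]).sum())
    return counts, het


def _log_table_prob_core(counts: np.ndarray, het: int) -> float:
    """log P({n_ij}|{n_a}) up to the arrangement-independent constant:
    h*log2 - sum log n_ij! (the n!, n_a!, (2n)! terms are constant)."""
    return het * np.log(2.0) - float(gammaln(counts[counts > 0] + 1).sum())


def hwe_exact_test(
    table: GenotypeTable,
    grouping: str,
    locus: str,
    population: str | None = None,
    steps: int = 10**6,
    dememorization: int = 10**6,
    seed: int = 0,
) -> HweResult | dict[str, HweResult]:
    """Conditional exact Hardy–Weinberg test, sampled by Markov chain.

    Returns one :class:`HweResult` when ``population`` is given, else a
    dict over all groups.  Monomorphic cells or cells with <2 individuals
    are flagged not applicable rather than silently given p = 1.
    """
    groups = _resolve_groups(table, grouping)
    if population is not None:
        groups = {population: groups[population]}
    j = table.locus_index(locus)
    out: dict[str, HweResult] = {}
    rng = np.random.default_rng(seed)
    for pop, rows in groups.items():
        gts = _locus_genotypes(table, rows, j)
        alleles = sort_alleles({a for g in gts for a in g.alleles})
        if len(gts) < 2 and len(alleles) >= 2:
            # single heterozygote: the only array with these counts
            out[pop] = HweResult(p=1.0, se=0.0, steps=0, applicable=True,
                                 note="single-state support")
            continue
        if len(alleles) < 2 or len(gts) < 2:
            out[pop] = HweResult(p=float("nan"), se=float("nan"), steps=0,
                                 applicable=False, note="monomorphic or too few")
            continue
        amap = {a: i for i, a in enumerate(alleles)}
        pairs = np.array([[amap[g.alleles[0]], amap[g.alleles[1]]] for g in gts])
        p, se, _ = _hwe_chain(pairs, len(alleles), steps, dememorization, rng,
                              statistic="prob")
        out[pop] = HweResult(p=p, se=se, steps=steps)
    if population is not None:
        return out[population]
    return out


def _hwe_chain(
    pairs: np.ndarray,
    k: int,
    steps: int,
    dememorization: int,
    rng: np.random.Generator,
    statistic: str,
) -> tuple[float, float, float]:
    """Run the transposition chain; return (p, MC-SE, observed statistic).

    ``statistic``: 'prob' counts states with conditional probability <=
    observed (two-sided exact test); 'het_le' / 'het_ge' count states whose
    heterozygote count is <= / >= the observed one (one-sided deficiency /
    excess tests with Ho as the statistic).
    """
    n = len(pairs)
    copies = pairs.reshape(-1).copy()  # 2n allele copies; pair t = (2t, 2t+1)
    counts, het = _table_stats(copies.reshape(-1, 2), k)
    logp = _log_table_prob_core(counts, het)
    obs_logp = logp
    obs_het = het
    tol = 1e-9

    total = dememorization + steps
    # pre-draw proposal indices in blocks to keep the python loop lean
    hits = 0
    hit_flags = np.empty(steps, dtype=bool) if steps > 0 else None
    block = 65536
    done = 0
    while done < total:
        m = min(block, total - done)
        ii = rng.integers(0, 2 * n, size=m)
        jj = rng.integers(0, 2 * n, size=m)
        for t in range(m):
            a_pos, b_pos = ii[t], jj[t]
            pa, pb = a_pos >> 1, b_pos >> 1
            if pa != pb:
                x, y = copies[a_pos], copies[b_pos]
                if x != y:
                    g1 = _ordered(copies[2 * pa], copies[2 * pa + 1])
                    g2 = _ordered(copies[2 * pb], copies[2 * pb + 1])
                    # remove the two old genotypes (sequential so coincident
                    # cells are handled): logp has a -sum log n_ij! term
                    logp += np.log(counts[g1])
                    counts[g1] -= 1
                    logp += np.log(counts[g2])
                    counts[g2] -= 1
                    het -= int(g1[0] != g1[1]) + int(g2[0] != g2[1])
                    copies[a_pos], copies[b_pos] = y, x
                    h1 = _ordered(copies[2 * pa], copies[2 * pa + 1])
                    h2 = _ordered(copies[2 * pb], copies[2 * pb + 1])
                    counts[h1] += 1
                    logp -= np.log(counts[h1])
                    counts[h2] += 1
                    logp -= np.log(counts[h2])
                    new_het = int(h1[0] != h1[1]) + int(h2[0] != h2[1])
                    d_het = new_het - int(g1[0] != g1[1]) - int(g2[0] != g2[1])
                    het += new_het
                    logp += d_het * np.log(2.0)
            step_idx = done + t
            if step_idx >= dememorization:
                s = step_idx - dememorization
                if statistic == "prob":
                    hit = logp <= obs_logp + tol
                elif statistic == "het_le":
                    hit = het <= obs_het
                else:
                    hit = het >= obs_het
                hit_flags[s] = hit
                hits += hit
        done += m

    p = hits / steps
    se = _batch_means_se(hit_flags)
    obs_stat = obs_logp if statistic == "prob" else float(obs_het)
    return p, se, obs_stat


def _ordered(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a <= b else (b, a)


def _batch_means_se(flags: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo SE of the hit rate by batch means (autocorrelation-aware)."""
    n = len(flags)
    if n < n_batches * 2:
        p = flags.mean()
        return float(np.sqrt(p * (1 - p) / max(n, 1)))
    usable = (n // n_batches) * n_batches
    means = flags[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def hwe_direction(
    table: GenotypeTable,
    grouping: str,
    locus: str,
    population: str,
    steps: int = 10**6,
    dememorization: int = 10**6,
    seed: int = 0,
    alpha: float = 0.05 / 15,
) -> dict:
    """One-sided heterozygote deficiency / excess tests.

    Uses the observed heterozygote count as the statistic against the same
    conditional null: deficiency p = P(Ho_sim <= Ho_obs), excess
    p = P(Ho_sim >= Ho_obs).  The reported direction is 'deficiency' or
    'excess' when the corresponding one-sided p falls below ``alpha``
    (the Bonferroni-adjusted level by default), else 'none'.
    """
    groups = _resolve_groups(table, grouping)
    j = table.locus_index(locus)
    gts = _locus_genotypes(table, groups[population], j)
    alleles = sort_alleles({a for g in gts for a in g.alleles})
    if len(alleles) < 2 or len(gts) < 2:
        return {"direction": "none", "p_deficiency": float("nan"),
                "p_excess": float("nan"), "applicable": False}
    amap = {a: i for i, a in enumerate(alleles)}
    pairs = np.array([[amap[g.alleles[0]], amap[g.alleles[1]]] for g in gts])
    rng = np.random.default_rng(seed)
    p_def, se_d, _ = _hwe_chain(pairs, len(alleles), steps, dememorization,
                                rng, "het_le")
    rng2 = np.random.default_rng(seed + 1)
    p_exc, se_e, _ = _hwe_chain(pairs, len(alleles), steps, dememorization,
                                rng2, "het_ge")
    if p_def < alpha:
        direction = "deficiency"
    elif p_exc < alpha:
        direction = "excess"
    else:
        direction = "none"
    return {"direction": direction, "p_deficiency": p_def, "p_excess": p_exc,
            "se_deficiency": se_d, "se_excess": se_e, "applicable": True}


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test level alpha / n_tests (0.05 / 15 = 0.00333 for a 15-locus panel)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# ML silent-allele estimation (EM)
# ---------------------------------------------------------------------------

@dataclass
class NullAlleleResult:
    null_freq: float
    visible_freqs: dict[str, float]
    loglik: float
    n_iter: int
    converged: bool


def null_allele_ml(
    table: GenotypeTable,
    grouping: str,
    locus: str,
    population: str,
    max_iter: int = 10**4,
    tol: float = 1e-8,
) -> NullAlleleResult:
    """EM estimate of the silent-allele frequency r at one locus.

    Genotype classes and their probabilities under visible frequencies p
    and null frequency r (p sums with r to 1): observed heterozygote i!=j:
    2 p_i p_j; apparent homozygote i: p_i^2 + 2 p_i r; missing: r^2.
    Missing calls are interpreted as null/null non-amplifications.
    """
    groups = _resolve_groups(table, grouping)
    j = table.locus_index(locus)
    rows = groups[population]
    het_counts: dict[tuple[str, str], int] = {}
    hom_counts: dict[str, int] = {}
    n_missing = 0
    for i in rows:
        g = table.calls[i][j]
        if g.triallelic:
            continue
        if g.missing:
            n_missing += 1
        elif g.heterozygous:
            het_counts[g.alleles] = het_counts.get(g.alleles, 0) + 1
        else:
            hom_counts[g.alleles[0]] = hom_counts.get(g.alleles[0], 0) + 1
    alleles = sort_alleles(
        set(hom_counts) | {a for pair in het_counts for a in pair}
    )
    if len(alleles) < 2:
        raise ValueError("locus needs >= 2 visible alleles for the null model")
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    n_total = sum(het_counts.values()) + sum(hom_counts.values()) + n_missing

    # initial values: uniform visible, small null
    p = np.full(k, (1.0 - 0.05) / k)
    r = 0.05
    ll_old = -np.inf
    n_iter = 0
    converged = False
    het_idx = [(idx[a], idx[b], c) for (a, b), c in het_counts.items()]
    hom_idx = [(idx[a], c) for a, c in hom_counts.items()]
    for n_iter in range(1, max_iter + 1):
        # E-step: expected allele-copy counts
        copies = np.zeros(k)
        null_copies = 0.0
        for ia, ib, c in het_idx:
            copies[ia] += c
            copies[ib] += c
        for ia, c in hom_idx:
            denom = p[ia] + 2.0 * r
            w_true = p[ia] / denom if denom > 0 else 1.0  # P(true hom | apparent)
            copies[ia] += c * (1.0 + w_true)
            null_copies += c * (1.0 - w_true)
        null_copies += 2.0 * n_missing
        # M-step
        total = 2.0 * n_total
        p = copies / total
        r = null_copies / total
        # log-likelihood of the class multinomial
        ll = 0.0
        for ia, ib, c in het_idx:
            ll += c * np.log(2.0 * p[ia] * p[ib])
        for ia, c in hom_idx:
            ll += c * np.log(p[ia] ** 2 + 2.0 * p[ia] * r)
        if n_missing:
            ll += n_missing * (2.0 * np.log(r) if r > 0 else -np.inf)
        if ll - ll_old < tol and np.isfinite(ll):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return NullAlleleResult(
        null_freq=float(r),
        visible_freqs={a: float(p[idx[a]]) for a in alleles},
        loglik=float(ll_old),
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Stage summary table
# ---------------------------------------------------------------------------

def diversity_table(
    table: GenotypeTable,
    grouping: str = "phylum",
    steps: int = 10**4,
    dememorization: int = 10**4,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(group, locus) Ho, He, HWE p, direction and null-allele estimate.

    The Bonferroni threshold is ``alpha / n_loci``.  Chain lengths default
    to desk scale; pass ``steps=10**6, dememorization=10**6`` for the full
    published settings.
    """
    het = heterozygosity(table, grouping)
    thr = bonferroni_threshold(alpha, table.n_loci)
    rows = []
    for rec in het.to_dict("records"):
        pop, locus = rec["population"], rec["locus"]
        res = hwe_exact_test(table, grouping, locus, population=pop,
                             steps=steps, dememorization=dememorization,
                             seed=seed)
        direction = {"direction": "none"}
        if res.applicable and res.p < thr:
            direction = hwe_direction(table, grouping, locus, pop,
                                      steps=steps,
                                      dememorization=dememorization,
                                      seed=seed + 1, alpha=thr)
        try:
            null = null_allele_ml(table, grouping, locus, pop)
            null_freq = null.null_freq
        except ValueError:
            null_freq = float("nan")
        rows.append({**rec, "hwe_p": res.p, "hwe_se": res.se,
                     "hwe_significant": res.applicable and res.p < thr,
                     "direction": direction["direction"],
                     "null_freq": null_freq})
    return pd.DataFrame(rows)
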