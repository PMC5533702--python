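"""Bayesian admixture clustering of multilocus genotypes.

The model is the standard admixture model with uncorrelated allele
frequencies: each individual i has ancestry proportions q_i on the
K-simplex, each allele copy independently picks a source cluster
z ~ Categorical(q_i) and then an allele from that cluster's frequency
vector p_{k,locus}.  Priors: p ~ Dirichlet(lambda) per (cluster, locus)
with lambda = 1 by default; q ~ Dirichlet(alpha * 1_K) with alpha either
fixed or given a uniform(0, 10) prior and updated by a Metropolis
random-walk.  All full conditionals are conjugate, so the sampler is a
plain Gibbs scheme; missing calls contribute nothing to any update.

The model log-likelihood estimate reported per run ("lnPD") is
mean(logL) - var(logL)/2 over the retained sweeps, where
logL = sum over scored allele copies of log sum_k q_ik p_k(allele).
Model order is selected with the Evanno second-difference statistic
DeltaK = mean|lnPD(K-1) - 2 lnPD(K) + lnPD(K+1)| / SD(lnPD(K)) over
replicate runs, and replicate label-switching is resolved by a greedy
column-correlation matching against a reference replicate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .strdata import GenotypeTable, encode_calls

__all__ = [
    "AdmixtureRun",
    "gibbs_admixture",
    "EvannoTable",
    "evanno",
    "align_replicates",
    "AncestryClassification",
    "classify_ancestry",
    "evaluate_structure_assignment",
]


@dataclass
class AdmixtureRun:
    K: int
    Q: np.ndarray                 # individuals x K posterior-mean ancestry
    P: np.ndarray                 # K x loci x max_alleles posterior means
    lnPD: float
    logL_trace: np.ndarray
    alpha_trace: np.ndarray
    seed: int
    loci: list[str] = field(default_factory=list)


def gibbs_admixture(
    table: GenotypeTable,
    K: int,
    burnin: int = 10_000,
    iters: int = 20_000,
    lam: float = 1.0,
    alpha_init: float = 1.0,
    update_alpha: bool = True,
    alpha_max: float = 10.0,
    alpha_sd: float = 0.05,
    seed: int = 0,
) -> AdmixtureRun:
    """Run the admixture Gibbs sampler and return posterior means.

    Defaults are desk-scale chain lengths; the full published protocol
    (burn-in 10^6, 10^5 sweeps) is reached by passing those values.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    codes, registries = encode_calls(table)
    n, L, _ = codes.shape
    sizes = np.array([len(r) for r in registries])
    if (sizes < 2).all():
        raise ValueError("need at least one polymorphic locus")
    A = int(sizes.max())
    rng = np.random.default_rng(seed)

    flat = codes.reshape(n, -1)                      # (n, 2L) allele codes
    valid = flat >= 0
    ii, cc = np.nonzero(valid)                       # individual, copy-slot
    ll = cc // 2                                     # locus of each scored copy
    aa = flat[ii, cc]
    M = len(ii)

    allele_mask = np.zeros((L, A), dtype=bool)
    for j, s in enumerate(sizes):
        allele_mask[j, :s] = True

    # init
    alpha = float(alpha_init)
    q = rng.dirichlet(np.ones(K), size=n)
    p = np.zeros((K, L, A))
    for k in range(K):
        g = rng.standard_gamma(lam, size=(L, A)) * allele_mask
        p[k] = g / g.sum(axis=1, keepdims=True)

    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L, A))
    logL_trace = np.empty(iters)
    alpha_trace = np.empty(iters)
    log_q_min = np.log(np.finfo(float).tiny)

    for sweep in range(burnin + iters):
        # z | q, p  — per scored copy, categorical over K
        pv = p[:, ll, aa]                            # (K, M)
        w = pv.T * q[ii]                             # (M, K)
        tot = w.sum(axis=1, keepdims=True)
        bad = tot[:, 0] <= 0
        if bad.any():
            w[bad] = 1.0 / K
            tot = w.sum(axis=1, keepdims=True)
        cw = np.cumsum(w, axis=1)
        u = rng.random(M) * tot[:, 0]
        z = (cw < u[:, None]).sum(axis=1)

        # p | z  — Dirichlet(lam + counts) per cluster x locus
        counts_p = np.zeros((K, L, A))
        np.add.at(counts_p, (z, ll, aa), 1.0)
        g = rng.standard_gamma(lam + counts_p) * allele_mask
        p = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)

        # q | z  — Dirichlet(alpha + counts) per individual
        counts_q = np.zeros((n, K))
        np.add.at(counts_q, (ii, z), 1.0)
        g = rng.standard_gamma(alpha + counts_q)
        q = g / np.maximum(g.sum(axis=1, keepdims=True), 1e-300)

        # alpha | q — Metropolis on uniform(0, alpha_max) prior
        if update_alpha and K > 1:
            prop = alpha + rng.normal(0.0, alpha_sd)
            if 0.0 < prop < alpha_max:
                logq = np.log(np.maximum(q, np.finfo(float).tiny))
                sum_logq = logq.sum()

                def dir_ll(a):
                    return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * sum_logq
                if np.log(rng.random()) < dir_ll(prop) - dir_ll(alpha):
                    alpha = prop

        if sweep >= burnin:
            t = sweep - burnin
            Q_sum += q
            P_sum += p
            mix = (p[:, ll, aa].T * q[ii]).sum(axis=1)
            logL_trace[t] = np.log(np.maximum(mix, 1e-300)).sum()
            alpha_trace[t] = alpha

    Q = Q_sum / iters
    P = P_sum / iters
    mean_l = float(logL_trace.mean())
    var_l = float(logL_trace.var())
    lnPD = mean_l - var_l / 2.0
    if not np.isfinite(lnPD):
        raise RuntimeError("non-finite likelihood in admixture sampler")
    return AdmixtureRun(K=K, Q=Q, P=P, lnPD=lnPD, logL_trace=logL_trace,
                        alpha_trace=alpha_trace, seed=seed,
                        loci=list(table.loci))


# ---------------------------------------------------------------------------
# Evanno model-order selection
# ---------------------------------------------------------------------------

@dataclass
class EvannoTable:
    table: pd.DataFrame     # K, mean_lnPD, sd_lnPD, delta_k
    selected_k: int | None

    def __repr__(self) -> str:
        return f"EvannoTable(selected_k={self.selected_k})\n{self.table}"


def evanno(runs: list[AdmixtureRun]) -> EvannoTable:
    """Evanno DeltaK over a collection of runs spanning K values.

    Requires >= 3 consecutive K values with >= 2 replicates each.  DeltaK
    is undefined (NaN) at boundary K and where the replicate SD is zero;
    the selected K is the argmax of DeltaK over defined interior values,
    ties broken toward smaller K.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.lnPD)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("need >= 2 replicates per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1] or sd[k] == 0.0:
            dk = float("nan")
        else:
            dk = abs(mean[k - 1] - 2.0 * mean[k] + mean[k + 1]) / sd[k]
        rows.append({"K": k, "mean_lnPD": mean[k], "sd_lnPD": sd[k],
                     "delta_k": dk})
    df = pd.DataFrame(rows)
    defined = df.dropna(subset=["delta_k"])
    selected = None
    if not defined.empty:
        best = defined["delta_k"].max()
        selected = int(defined.loc[defined["delta_k"] >= best - 1e-12, "K"].min())
    return EvannoTable(table=df, selected_k=selected)


# ---------------------------------------------------------------------------
# Replicate alignment (label switching)
# ---------------------------------------------------------------------------

def _greedy_permutation(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """perm such that Q[:, perm] best matches Q_ref, greedy by correlation.

    Degenerate (constant) columns have undefined correlation; they score
    -inf and are matched last.
    """
    K = Q.shape[1]
    corr = np.full((K, K), -np.inf)
    for a in range(K):
        for b in range(K):
            x, y = Q_ref[:, a], Q[:, b]
            if x.std() > 0 and y.std() > 0:
                corr[a, b] = float(np.corrcoef(x, y)[0, 1])
    perm = np.full(K, -1)
    used_b = set()
    order = sorted(
        ((corr[a, b], a, b) for a in range(K) for b in range(K)),
        reverse=True,
    )
    for _, a, b in order:
        if perm[a] == -1 and b not in used_b:
            perm[a] = b
            used_b.add(b)
    for a in range(K):          # degenerate leftovers
        if perm[a] == -1:
            perm[a] = next(b for b in range(K) if b not in used_b)
            used_b.add(perm[a])
    return perm


def align_replicates(runs: list[AdmixtureRun]) -> tuple[list[AdmixtureRun], np.ndarray]:
    """Align cluster labels of replicate runs to the first one.

    Returns the aligned runs (columns of Q and first axis of P permuted)
    and the consensus Q (mean of the aligned matrices).
    """
    if not runs:
        raise ValueError("no runs")
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must share K")
    ref = runs[0]
    aligned = [ref]
    for r in runs[1:]:
        perm = _greedy_permutation(ref.Q, r.Q)
        aligned.append(
            AdmixtureRun(K=K, Q=r.Q[:, perm], P=r.P[perm], lnPD=r.lnPD,
                         logL_trace=r.logL_trace, alpha_trace=r.alpha_trace,
                         seed=r.seed, loci=r.loci)
        )
    consensus = np.mean([r.Q for r in aligned], axis=0)
    return aligned, consensus


# ---------------------------------------------------------------------------
# 0.7-cut-off classification and its evaluation
# ---------------------------------------------------------------------------

@dataclass
class AncestryClassification:
    """Per-individual group under the ancestry-proportion cut-off.

    ``group[i]`` is 0 (majority cluster A), 1 (majority cluster B) or
    2 (admixed: no cluster reaches the threshold).
    """

    group: np.ndarray
    threshold: float

    @property
    def n_admixed(self) -> int:
        return int((self.group == 2).sum())


def classify_ancestry(Q: np.ndarray, threshold: float = 0.7) -> AncestryClassification:
    """Three-way grouping of a K=2 ancestry matrix.

    Cluster-A proportion >= threshold -> group 0; cluster-B proportion >=
    threshold -> group 1; otherwise admixed (group 2).  The boundary is
    inclusive.
    """
    Q = np.asarray(Q)
    if Q.ndim != 2 or Q.shape[1] != 2:
        raise ValueError("classification requires a K=2 ancestry matrix")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    group = np.full(len(Q), 2, dtype=int)
    group[Q[:, 0] >= threshold] = 0
    group[Q[:, 1] >= threshold] = 1
    return AncestryClassification(group=group, threshold=threshold)


def evaluate_structure_assignment(
    classification: AncestryClassification,
    declared: list[str],
) -> pd.DataFrame:
    """Assignment summary per self-declared group.

    Maps each cluster to the declared label holding the majority of the
    individuals classified to it, then tabulates per declared group: the
    counts classified to each cluster, and the percentages not assigned
    (admixed), correctly assigned, and wrongly assigned.  Raises if both
    clusters map to the same declared label (ambiguous mapping).
    """
    declared = list(declared)
    if len(declared) != len(classification.group):
        raise ValueError("labels must cover all individuals")
    g = classification.group
    cluster_label: dict[int, str] = {}
    for k in (0, 1):
        members = [declared[i] for i in np.nonzero(g == k)[0]]
        if members:
            vals, cnts = np.unique(members, return_counts=True)
            cluster_label[k] = str(vals[np.argmax(cnts)])
    if len(cluster_label) == 2 and cluster_label[0] == cluster_label[1]:
        raise ValueError("ambiguous cluster-to-label mapping: both clusters "
                         f"majority {cluster_label[0]!r}")
    rows = []
    for lab in sorted(set(declared)):
        idx = [i for i, d in enumerate(declared) if d == lab]
        size = len(idx)
        n0 = sum(g[i] == 0 for i in idx)
        n1 = sum(g[i] == 1 for i in idx)
        n_adm = sum(g[i] == 2 for i in idx)
        correct = sum(
            1 for i in idx if g[i] in cluster_label and cluster_label[g[i]] == lab
        )
        wrong = size - n_adm - correct
        rows.append({
            "declared": lab, "n": size,
            "to_cluster_A": n0, "to_cluster_B": n1,
            "pct_not_assigned": 100.0 * n_adm / size,
            "pct_correct": 100.0 * correct / size,
            "pct_error": 100.0 * wrong / size,
        })
    return pd.DataFrame(rows)
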