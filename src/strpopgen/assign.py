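"""Frequency-based population assignment and locus informativeness.

Assignment follows the critical-population log-likelihood rule: for each
baseline population the log10 likelihood of an individual's multilocus
genotype is the sum over scored loci of the log10 Hardy–Weinberg genotype
probability (2 p_i p_j for heterozygotes, p_i^2 for homozygotes) under
that population's allele frequencies.  The individual is assigned to the
maximum-likelihood population when the log10 likelihood ratio between the
best and second-best population reaches the threshold (default
log10 3 = 0.477, boundary inclusive); otherwise it is "not assigned" and
treated as admixed.

Baselines are built from the non-admixed individuals only (the two
majority-ancestry groups of the clustering stage).  Any allele present
somewhere in the full table but unseen in a baseline population receives
frequency 1 / (2 n_pop + 1) before renormalization, so a single private
allele cannot force an infinite likelihood ratio.

Locus informativeness for ancestry is Rosenberg's I_n,

    I_n = sum_alleles ( -pbar ln pbar + (1/K) sum_pops p ln p ),

with pbar the across-population mean frequency and 0 ln 0 = 0; it ranges
from 0 (identical frequencies) to ln K (populations fixed for different
alleles), i.e. ln 2 = 0.693 for a two-population baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admixture import AncestryClassification
from .diversity import AlleleFrequencyTable, allele_frequencies
from .strdata import GenotypeTable

__all__ = [
    "build_baseline",
    "AssignmentRecord",
    "loglik_assign",
    "assign_table",
    "evaluate_assignment",
    "informativeness",
    "informativeness_summary",
    "LOG10_3",
]

LOG10_3 = math.log10(3.0)


def build_baseline(
    table: GenotypeTable,
    classification: AncestryClassification,
    labels: tuple[str, str] = ("A", "B"),
) -> AlleleFrequencyTable:
    """Allele frequencies of the two non-admixed training groups.

    Individuals in the admixed group are excluded.  Unseen-allele
    smoothing: every allele observed anywhere in ``table`` but absent
    from a baseline population gets 1 / (2 n_pop + 1), after which the
    population's frequencies are renormalized to 1.
    """
    g = classification.group
    if len(g) != table.n_individuals:
        raise ValueError("classification does not cover the table")
    rows_a = np.nonzero(g == 0)[0]
    rows_b = np.nonzero(g == 1)[0]
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise ValueError("both baseline groups must be non-empty")

    freqs: dict[tuple[str, str], dict[str, float]] = {}
    sizes: dict[tuple[str, str], int] = {}
    for lab, rows in zip(labels, (rows_a, rows_b)):
        sub = table.subset(list(rows))
        aft = allele_frequencies(sub, grouping="all")
        for locus in table.loci:
            cell = aft.freqs.get(("all", locus))
            if cell is None:
                continue
            n_copies = aft.sample_sizes[("all", locus)]
            registry = table.allele_registry(locus)
            smoothed = dict(cell)
            eps = 1.0 / (n_copies + 1)   # = 1/(2 n_pop + 1) per unseen allele
            for a in registry:
                if a not in smoothed:
                    smoothed[a] = eps
            total = sum(smoothed.values())
            freqs[(lab, locus)] = {a: f / total for a, f in smoothed.items()}
            sizes[(lab, locus)] = n_copies
    return AlleleFrequencyTable(list(labels), list(table.loci), freqs, sizes)


@dataclass
class AssignmentRecord:
    individual: str
    log10_lik: dict[str, float]
    log10_lr: float                 # best minus second-best
    decision: str                   # 'assigned:<pop>' | 'not_assigned'
    best: str | None
    n_loci_used: int

    @property
    def assigned(self) -> bool:
        return self.decision.startswith("assigned:")


def loglik_assign(
    table: GenotypeTable,
    individual_index: int,
    baseline: AlleleFrequencyTable,
    threshold: float = LOG10_3,
) -> AssignmentRecord:
    """Assign one individual by the log10 likelihood-ratio rule."""
    ind = table.individuals[individual_index]
    logliks = {pop: 0.0 for pop in baseline.populations}
    used = 0
    for j, locus in enumerate(table.loci):
        g = table.calls[individual_index][j]
        if g.missing or g.triallelic:
            continue
        cells = [(pop, baseline.freqs.get((pop, locus)))
                 for pop in baseline.populations]
        if any(c is None for _, c in cells):
            continue
        used += 1
        a, b = g.alleles
        for pop, cell in cells:
            pa = cell.get(a, 0.0)
            pb = cell.get(b, 0.0)
            prob = pa * pa if a == b else 2.0 * pa * pb
            logliks[pop] += math.log10(prob) if prob > 0 else -math.inf
    if used == 0:
        return AssignmentRecord(ind.id, logliks, float("nan"),
                                "not_assigned", None, 0)
    ranked = sorted(logliks.items(), key=lambda kv: kv[1], reverse=True)
    lr = ranked[0][1] - ranked[1][1]
    if lr >= threshold:
        return AssignmentRecord(ind.id, logliks, lr,
                                f"assigned:{ranked[0][0]}", ranked[0][0], used)
    return AssignmentRecord(ind.id, logliks, lr, "not_assigned", None, used)


def assign_table(
    table: GenotypeTable,
    baseline: AlleleFrequencyTable,
    threshold: float = LOG10_3,
) -> list[AssignmentRecord]:
    """Assign every individual of the table against the baseline."""
    return [loglik_assign(table, i, baseline, threshold)
            for i in range(table.n_individuals)]


def evaluate_assignment(
    records: list[AssignmentRecord],
    declared: list[str],
) -> pd.DataFrame:
    """Per-declared-group assignment summary (counts and percentages).

    The error rate is the share of the declared group assigned to a
    population other than the declared one; "not assigned" individuals are
    counted as admixed, not as errors.
    """
    if len(records) != len(declared):
        raise ValueError("labels must cover all records")
    pops = records[0].log10_lik.keys() if records else []
    rows = []
    for lab in sorted(set(declared)):
        idx = [i for i, d in enumerate(declared) if d == lab]
        size = len(idx)
        counts = {p: 0 for p in pops}
        n_not = 0
        correct = 0
        for i in idx:
            r = records[i]
            if not r.assigned:
                n_not += 1
            else:
                counts[r.best] += 1
                if r.best == lab:
                    correct += 1
        wrong = size - n_not - correct
        row = {"declared": lab, "n": size}
        row.update({f"to_{p}": c for p, c in counts.items()})
        row.update({
            "pct_not_assigned": 100.0 * n_not / size,
            "pct_correct": 100.0 * correct / size,
            "pct_error": 100.0 * wrong / size,
        })
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rosenberg informativeness for assignment
# ---------------------------------------------------------------------------

def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def informativeness(baseline: AlleleFrequencyTable) -> pd.DataFrame:
    """I_n per locus over the baseline's K populations (natural log)."""
    K = len(baseline.populations)
    if K < 2:
        raise ValueError("informativeness requires >= 2 populations")
    rows = []
    for locus in baseline.loci:
        cells = [baseline.freqs.get((pop, locus)) for pop in baseline.populations]
        if any(c is None for c in cells):
            continue
        alleles = sorted({a for c in cells for a in c})
        P = np.array([[c.get(a, 0.0) for a in alleles] for c in cells])
        pbar = P.mean(axis=0)
        i_n = float((-_xlogx(pbar) + _xlogx(P).mean(axis=0)).sum())
        rows.append({"locus": locus, "I_n": i_n, "K": K})
    return pd.DataFrame(rows)


def informativeness_summary(info: pd.DataFrame) -> dict:
    """Mean and sample SD of I_n across loci plus the ranked table."""
    vals = info["I_n"].to_numpy()
    if len(vals) == 0:
        raise ValueError("no loci")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    ranked = info.sort_values("I_n", ascending=False).reset_index(drop=True)
    return {"mean": float(vals.mean()), "sd": sd, "ranked": ranked}
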