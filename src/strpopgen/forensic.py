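"""Forensic summary statistics for STR panels.

Per-locus parameters, with h and H the relative frequencies of
heterozygous and homozygous genotypes among non-missing calls
(h + H = 1), p_i the allele frequencies and P_g the observed
genotype-class frequencies:

    PE  = h^2 (1 - 2 h H^2)           power of exclusion
    MP  = sum_g P_g^2                 match probability
    PD  = 1 - MP                      power of discrimination
    TPI = (H + h) / (2 H)             typical paternity index
    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2   (Botstein)

Combined over a panel of unlinked loci:

    CPE = 1 - prod_i (1 - PE_i),  CMP = prod_i MP_i,  CPD = 1 - CMP

A locus with no homozygotes has PE = 1 (hence CPE = 1 for the whole
panel) and an infinite paternity index, which is flagged rather than
raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strdata import GenotypeTable

__all__ = [
    "power_of_exclusion",
    "match_probability",
    "power_of_discrimination",
    "typical_paternity_index",
    "pic",
    "LocusForensics",
    "ForensicSummary",
    "combine",
    "forensic_summary",
]

_HH_TOL = 1e-9


def _check_hH(h: float, H: float) -> None:
    if not (0.0 <= h <= 1.0 and 0.0 <= H <= 1.0):
        raise ValueError("h and H must be relative frequencies in [0, 1]")
    if abs(h + H - 1.0) > _HH_TOL:
        raise ValueError(f"h + H must equal 1 (got {h + H})")


def power_of_exclusion(h: float, H: float) -> float:
    """PE = h^2 (1 - 2 h H^2) from heterozygote/homozygote frequencies."""
    _check_hH(h, H)
    return h**2 * (1.0 - 2.0 * h * H**2)


def power_of_discrimination(mp: float) -> float:
    """PD = 1 - MP."""
    if not 0.0 <= mp <= 1.0:
        raise ValueError("MP must be in [0, 1]")
    return 1.0 - mp


def typical_paternity_index(h: float, H: float) -> float:
    """TPI = (H + h) / (2 H); returns ``math.inf`` when H = 0."""
    _check_hH(h, H)
    if H == 0.0:
        return math.inf
    return (H + h) / (2.0 * H)


def pic(freqs) -> float:
    """Polymorphic information content (Botstein) of an allele frequency vector."""
    p = np.asarray(list(freqs), dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must sum to 1")
    s2 = float(np.sum(p**2))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2**2 - s4)


def match_probability(
    table: GenotypeTable,
    grouping: str,
    locus: str,
    population: str | None = None,
    expected: bool = False,
) -> float:
    """MP = sum over genotype classes of the squared class frequency.

    By default classes are the *observed* genotype frequencies; with
    ``expected=True`` the Hardy–Weinberg expected genotype frequencies
    (2 p_i p_j, p_i^2) from the allele frequencies are used instead.
    """
    _, counts, n = _genotype_classes(table, grouping, locus, population)
    if n == 0:
        raise ValueError(f"no non-missing genotypes at {locus!r}")
    if not expected:
        return sum((c / n) ** 2 for c in counts.values())
    allele_counts: dict[str, int] = {}
    for (a, b), c in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    m = 2 * n
    p = {a: c / m for a, c in allele_counts.items()}
    labs = list(p)
    mp = 0.0
    for i, a in enumerate(labs):
        for b in labs[i:]:
            g = p[a] ** 2 if a == b else 2 * p[a] * p[b]
            mp += g**2
    return mp


def _genotype_classes(table, grouping, locus, population):
    if grouping == "all":
        rows = list(range(table.n_individuals))
    else:
        groups = table.group_indices(grouping)
        if population is None:
            raise ValueError("population required for grouped tables")
        rows = groups[population]
    j = table.locus_index(locus)
    counts: dict[tuple[str, str], int] = {}
    n = 0
    for i in rows:
        g = table.calls[i][j]
        if g.missing or g.triallelic:
            continue
        counts[g.alleles] = counts.get(g.alleles, 0) + 1
        n += 1
    return rows, counts, n


@dataclass
class LocusForensics:
    locus: str
    h: float
    H: float
    PE: float
    MP: float
    PD: float
    TPI: float  # math.inf when no homozygotes observed
    PIC: float
    n: int


@dataclass
class ForensicSummary:
    """Per-locus forensic parameters plus the combined panel values."""

    population: str
    loci: list[LocusForensics]
    CPE: float
    CMP: float
    CPD: float
    excluded_loci: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": lf.locus, "n": lf.n, "PE": lf.PE, "MP": lf.MP,
             "PD": lf.PD, "TPI": lf.TPI, "PIC": lf.PIC}
            for lf in self.loci
        ]
        rows.append({"locus": "combined", "n": np.nan, "PE": self.CPE,
                     "MP": self.CMP, "PD": self.CPD, "TPI": np.nan,
                     "PIC": np.nan})
        return pd.DataFrame(rows)


def combine(entries: list[LocusForensics]) -> tuple[float, float, float]:
    """CPE = 1 - prod(1 - PE_i); CMP = prod MP_i; CPD = 1 - CMP."""
    if not entries:
        raise ValueError("need at least one usable locus")
    cpe = 1.0
    cmp_ = 1.0
    for e in entries:
        cpe *= 1.0 - e.PE
        cmp_ *= e.MP
    return 1.0 - cpe, cmp_, 1.0 - cmp_


def forensic_summary(
    table: GenotypeTable,
    grouping: str = "all",
    population: str | None = None,
    expected_mp: bool = False,
) -> ForensicSummary:
    """Compute all per-locus parameters and the combined CPE/CMP/CPD.

    Loci with no usable genotypes in the cell are excluded from the
    combination and listed in ``excluded_loci``.
    """
    entries: list[LocusForensics] = []
    excluded: list[str] = []
    for locus in table.loci:
        try:
            _, counts, n = _genotype_classes(table, grouping, locus, population)
        except KeyError:
            raise
        if n == 0:
            excluded.append(locus)
            continue
        n_het = sum(c for (a, b), c in counts.items() if a != b)
        h = n_het / n
        H = 1.0 - h
        allele_counts: dict[str, int] = {}
        for (a, b), c in counts.items():
            allele_counts[a] = allele_counts.get(a, 0) + c
            allele_counts[b] = allele_counts.get(b, 0) + c
        p = np.array(list(allele_counts.values()), dtype=float)
        p /= p.sum()
        mp = match_probability(table, grouping, locus, population,
                               expected=expected_mp)
        entries.append(
            LocusForensics(
                locus=locus, h=h, H=H,
                PE=power_of_exclusion(h, H),
                MP=mp,
                PD=power_of_discrimination(mp),
                TPI=typical_paternity_index(h, H),
                PIC=pic(p),
                n=n,
            )
        )
    cpe, cmp_, cpd = combine(entries)
    return ForensicSummary(
        population=population or "all",
        loci=entries, CPE=cpe, CMP=cmp_, CPD=cpd, excluded_loci=excluded,
    )
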