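"""Synthetic STR genotype generator with known population structure.

Generates diploid genotype tables under the Balding–Nichols divergence
model: ancestral allele frequencies are drawn from a flat Dirichlet and each
descendant population's frequencies from ``Dirichlet(p_anc * (1 - F) / F)``,
which has mean ``p_anc`` and Wright's fixation index exactly ``F`` in
expectation — so the differentiation of the simulated data can be calibrated
to a target FST analytically, without real genotypes.

Individual-level admixture, silent (null) alleles, microvariant allele
labels, missing data, and ethno-linguistic / district labelling are layered
on top so that every downstream stage of the analysis (diversity, forensic,
differentiation, clustering, assignment) can be exercised and validated
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .strdata import DISTRICTS, Genotype, GenotypeTable, Individual, MISSING

__all__ = [
    "PopulationLabels",
    "SimulationConfig",
    "SimulationTruth",
    "simulate",
    "botswana_preset",
    "IDENTIFILER_LOCI",
]

#: the 15 autosomal loci of the Identifiler panel (Amelogenin excluded:
#: sex typing is metadata, never a statistical locus)
IDENTIFILER_LOCI = [
    "D8S1179", "D21S11", "D7S820", "CSF1PO", "D3S1358", "TH01", "D13S317",
    "D16S539", "D2S1338", "D19S433", "vWA", "TPOX", "D18S51", "D5S818", "FGA",
]


@dataclass
class PopulationLabels:
    """How one simulated ancestral population is labelled in metadata."""

    phylum: str = "unknown"
    subgroup_weights: dict[str, float] | None = None
    district_weights: dict[str, float] | None = None


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``fst`` is the Balding–Nichols differentiation of each population from
    the common ancestor, in [0, 1).  ``admixture_alpha`` is the symmetric
    Dirichlet concentration for individual ancestry proportions; 0 disables
    admixture (each individual belongs discretely to its labelled
    population).  ``null_rate`` is the per-transmitted-allele silent-allele
    probability; a visible/null pair is observed as an apparent homozygote,
    a null/null pair as a missing call.
    """

    n_pops: int = 2
    pop_sizes: Sequence[int] = (100, 100)
    n_loci: int = 15
    alleles_per_locus: int | Sequence[int] = 8
    fst: float = 0.0
    admixture_alpha: float = 0.0
    null_rate: float = 0.0
    microvariant_fraction: float = 0.0
    missing_rate: float = 0.0
    label_plan: Sequence[PopulationLabels] | None = None
    locus_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if any(s <= 0 for s in self.pop_sizes):
            raise ValueError("pop_sizes must be positive")
        for name, val in [
            ("fst", self.fst),
            ("null_rate", self.null_rate),
            ("microvariant_fraction", self.microvariant_fraction),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0.0 <= val < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.admixture_alpha < 0:
            raise ValueError("admixture_alpha must be >= 0")
        if self.label_plan is not None and len(self.label_plan) != self.n_pops:
            raise ValueError("label_plan must have one entry per population")

    @property
    def alleles_list(self) -> list[int]:
        if isinstance(self.alleles_per_locus, int):
            return [self.alleles_per_locus] * self.n_loci
        out = list(self.alleles_per_locus)
        if len(out) != self.n_loci:
            raise ValueError("alleles_per_locus list must match n_loci")
        return out


@dataclass
class SimulationTruth:
    """Ground truth of one simulated table, for recovery tests.

    ``ancestral_freqs[j]`` and ``pop_freqs[k][j]`` are frequency vectors
    over the locus-j allele registry ``allele_labels[j]``; ``q`` is the
    (n_individuals, K) true ancestry matrix; ``null_mask`` flags the
    transmitted allele copies that were silent.
    """

    allele_labels: list[list[str]]
    ancestral_freqs: list[np.ndarray]
    pop_freqs: list[list[np.ndarray]]
    q: np.ndarray
    null_mask: np.ndarray

    def expected_heterozygosity(self, pop: int, locus: int) -> float:
        p = self.pop_freqs[pop][locus]
        return float(1.0 - np.sum(p**2))


def _make_labels(n_alleles: int, micro_fraction: float, rng: np.random.Generator) -> list[str]:
    """Repeat-count labels starting at 6; a random subset get a '.3' part."""
    base = [str(6 + i) for i in range(n_alleles)]
    n_micro = int(round(micro_fraction * n_alleles))
    if n_micro:
        idx = rng.choice(n_alleles, size=n_micro, replace=False)
        for i in idx:
            base[i] = base[i] + ".3"
    return base


def simulate(config: SimulationConfig) -> tuple[GenotypeTable, SimulationTruth]:
    """Draw one genotype table plus its ground truth, reproducibly from seed.

    Each allele copy of an admixed individual picks its source population
    from the individual's true ancestry ``q`` and then an allele from that
    population's frequency vector; with ``admixture_alpha > 0`` the ancestry
    is Dirichlet-distributed with the largest component aligned to the
    individual's labelled population, so labels remain the majority ancestry.
    """
    rng = np.random.default_rng(config.seed)
    K, L = config.n_pops, config.n_loci
    alleles = config.alleles_list
    labels = [_make_labels(a, config.microvariant_fraction, rng) for a in alleles]

    anc: list[np.ndarray] = []
    popf: list[list[np.ndarray]] = [[] for _ in range(K)]
    for j in range(L):
        p_anc = rng.dirichlet(np.ones(alleles[j]))
        # numerical floor: Dirichlet parameters must be positive
        p_anc = np.clip(p_anc, 1e-9, None)
        p_anc /= p_anc.sum()
        anc.append(p_anc)
        for k in range(K):
            if config.fst == 0.0:
                popf[k].append(p_anc.copy())
            else:
                conc = p_anc * (1.0 - config.fst) / config.fst
                popf[k].append(rng.dirichlet(conc))

    N = int(sum(config.pop_sizes))
    own = np.repeat(np.arange(K), config.pop_sizes)
    if config.admixture_alpha > 0:
        q = rng.dirichlet(np.full(K, config.admixture_alpha), size=N)
        # align the majority component with the labelled population
        for i in range(N):
            jmax = int(np.argmax(q[i]))
            if jmax != own[i]:
                q[i, [own[i], jmax]] = q[i, [jmax, own[i]]]
    else:
        q = np.zeros((N, K))
        q[np.arange(N), own] = 1.0

    null_mask = np.zeros((N, L, 2), dtype=bool)
    plan = config.label_plan
    names = list(config.locus_names) if config.locus_names else [
        f"L{j + 1:02d}" for j in range(L)
    ]

    individuals: list[Individual] = []
    calls: list[list[Genotype]] = []
    for i in range(N):
        k_own = own[i]
        if plan is not None:
            pl = plan[k_own]
            phylum = pl.phylum
            subgroup = _weighted_choice(pl.subgroup_weights, rng)
            district = _weighted_choice(pl.district_weights, rng)
        else:
            phylum = "unknown"
            subgroup = "unknown"
            district = "unknown"
        sex = "F" if rng.random() < 0.5 else "M"
        individuals.append(
            Individual(id=f"S{i + 1:04d}", phylum=phylum, subgroup=subgroup,
                       district=district, sex=sex)
        )
        row: list[Genotype] = []
        for j in range(L):
            copies: list[str | None] = []
            for c in range(2):
                src = rng.choice(K, p=q[i]) if config.admixture_alpha > 0 else k_own
                a = rng.choice(alleles[j], p=popf[src][j])
                if config.null_rate > 0 and rng.random() < config.null_rate:
                    null_mask[i, j, c] = True
                    copies.append(None)
                else:
                    copies.append(labels[j][a])
            if config.missing_rate > 0 and rng.random() < config.missing_rate:
                row.append(MISSING)
            elif copies[0] is None and copies[1] is None:
                row.append(MISSING)  # null/null: no amplification
            elif copies[0] is None:
                row.append(Genotype((copies[1], copies[1])))  # apparent homozygote
            elif copies[1] is None:
                row.append(Genotype((copies[0], copies[0])))
            else:
                row.append(Genotype((copies[0], copies[1])))
        calls.append(row)

    table = GenotypeTable(names, individuals, calls)
    truth = SimulationTruth(labels, anc, popf, q, null_mask)
    return table, truth


def _weighted_choice(weights: dict[str, float] | None, rng: np.random.Generator) -> str:
    if not weights:
        return "unknown"
    keys = list(weights)
    w = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def botswana_preset(seed: int = 0) -> SimulationConfig:
    """Study-design preset: 752 Bantu + 238 Khoisan, 15 loci, FST 0.01213.

    Two ancestral populations sized as the self-declared Bantu and Khoisan
    samples; the 15 Identifiler autosomal loci with 8 alleles each and a
    microvariant fraction exercising fractional labels; moderate
    individual-level admixture; simulated Khoisan concentrated in the
    Ghanzi and North-west districts, Bantu spread across all nine.
    """
    bantu = PopulationLabels(
        phylum="Bantu",
        subgroup_weights={"Central-K": 0.25, "Central-R": 0.15, "Central-S": 0.60},
        district_weights={d: 1.0 for d in DISTRICTS},
    )
    khoisan = PopulationLabels(
        phylum="Khoisan",
        subgroup_weights={"Khoe-Kwadi": 0.45, "Kx'a": 0.30, "Tuu": 0.25},
        district_weights={"Ghanzi": 0.45, "North-west": 0.35, "Kgalagadi": 0.10,
                          "Central": 0.05, "Southern": 0.05},
    )
    return SimulationConfig(
        n_pops=2,
        pop_sizes=(752, 238),
        n_loci=15,
        alleles_per_locus=8,
        fst=0.01213,
        admixture_alpha=0.25,
        null_rate=0.0,
        microvariant_fraction=0.1,
        missing_rate=0.0,
        label_plan=[bantu, khoisan],
        locus_names=IDENTIFILER_LOCI,
        seed=seed,
    )
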