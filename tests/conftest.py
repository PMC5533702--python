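import numpy as np
import pytest

from strpopgen.strdata import Genotype, GenotypeTable, Individual, MISSING


def make_random_table(
    rng: np.random.Generator,
    n_individuals: int = 12,
    n_loci: int = 4,
    alleles=("8", "9", "9.3", "10", "11"),
    missing_rate: float = 0.1,
    phyla=("Bantu", "Khoisan"),
) -> GenotypeTable:
    """Random genotype table exercising microvariants and missing calls."""
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    individuals = []
    calls = []
    for i in range(n_individuals):
        individuals.append(
            Individual(
                id=f"I{i:03d}",
                phylum=phyla[i % len(phyla)],
                sex="F" if rng.random() < 0.5 else "M",
            )
        )
        row = []
        for _ in range(n_loci):
            if rng.random() < missing_rate:
                row.append(MISSING)
            else:
                a, b = rng.choice(alleles, size=2)
                row.append(Genotype((str(a), str(b))))
        calls.append(row)
    return GenotypeTable(loci, individuals, calls)


def hwe_table(
    rng: np.random.Generator,
    freqs,
    n: int,
    labels=None,
) -> GenotypeTable:
    """Single-locus table drawn exactly under Hardy-Weinberg proportions."""
    freqs = np.asarray(freqs, dtype=float)
    labels = labels or [str(8 + i) for i in range(len(freqs))]
    individuals = [Individual(id=f"H{i}") for i in range(n)]
    draws = rng.choice(len(freqs), size=(n, 2), p=freqs / freqs.sum())
    calls = [[Genotype((labels[a], labels[b]))] for a, b in draws]
    return GenotypeTable(["LOC"], individuals, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
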