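"""Diversity stage: frequencies, heterozygosity, HWE exact tests, null EM.

The HWE oracle enumerates every arrangement of the allele copies into
diploid genotypes (all permutations of the copy multiset, paired
adjacently); arrangements are equiprobable under the conditional null, so
a genotype table's conditional probability is proportional to the number
of arrangements mapping to it.  The oracle therefore never touches the
package's probability formula.
"""

import itertools
from collections import Counter

import numpy as np
import pytest

from strpopgen.diversity import (
    allele_frequencies,
    bonferroni_threshold,
    heterozygosity,
    hwe_direction,
    hwe_exact_test,
    null_allele_ml,
)
from strpopgen.simgen import SimulationConfig, simulate
from strpopgen.strdata import Genotype, GenotypeTable, Individual, MISSING

from conftest import hwe_table


def single_locus_table(genotypes):
    inds = [Individual(id=f"x{i}") for i in range(len(genotypes))]
    calls = [[Genotype((a, b)) if a is not None else MISSING]
             for a, b in genotypes]
    return GenotypeTable(["LOC"], inds, calls)


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_null(copies):
    """Exact conditional distribution over genotype tables.

    Returns {table_key: count} over all permutations of the copy multiset,
    where table_key is the sorted tuple of sorted genotype pairs.
    """
    tables = Counter()
    for perm in itertools.permutations(copies):
        pairs = tuple(sorted(tuple(sorted(perm[i:i + 2]))
                             for i in range(0, len(perm), 2)))
        tables[pairs] += 1
    return tables


def oracle_p_two_sided(genotypes):
    copies = [a for g in genotypes for a in g]
    obs = tuple(sorted(tuple(sorted(g)) for g in genotypes))
    tables = enumerate_null(copies)
    total = sum(tables.values())
    c_obs = tables[obs]
    return sum(c for c in tables.values() if c <= c_obs) / total


def oracle_p_one_sided(genotypes, side):
    copies = [a for g in genotypes for a in g]
    obs = tuple(sorted(tuple(sorted(g)) for g in genotypes))
    h_obs = sum(a != b for a, b in obs)
    tables = enumerate_null(copies)
    total = sum(tables.values())
    hit = 0
    for t, c in tables.items():
        h = sum(a != b for a, b in t)
        if (side == "le" and h <= h_obs) or (side == "ge" and h >= h_obs):
            hit += c
    return hit / total


def all_instances(max_individuals=3, n_alleles=3):
    """Every genotype array with <= max_individuals over n_alleles labels."""
    labels = [str(8 + i) for i in range(n_alleles)]
    genos = list(itertools.combinations_with_replacement(labels, 2))
    for n in range(2, max_individuals + 1):
        for combo in itertools.combinations_with_replacement(genos, n):
            present = {a for g in combo for a in g}
            if len(present) >= 2:
                yield list(combo)


# ---------------------------------------------------------------------------
# Frequencies and heterozygosity
# ---------------------------------------------------------------------------

class TestFrequencies:
    def test_monomorphic_counts(self):
        t = single_locus_table([("10", "10")] * 4)
        aft = allele_frequencies(t, "all")
        assert aft.freqs[("all", "LOC")] == {"10": 1.0}
        assert aft.sample_sizes[("all", "LOC")] == 8

    def test_direct_count(self):
        t = single_locus_table([("9", "10"), ("10", "10")])
        f = allele_frequencies(t, "all").freqs[("all", "LOC")]
        assert f == {"9": 0.25, "10": 0.75}

    def test_missing_excluded(self):
        t = single_locus_table([("9", "10"), (None, None)])
        aft = allele_frequencies(t, "all")
        assert aft.sample_sizes[("all", "LOC")] == 2

    def test_consistency_on_simulation(self):
        """Estimated frequencies converge to the simulating truth."""
        cfg = SimulationConfig(n_pops=1, pop_sizes=(5000,), n_loci=3,
                               alleles_per_locus=5, seed=9)
        table, truth = simulate(cfg)
        aft = allele_frequencies(table, "all")
        for j, locus in enumerate(table.loci):
            f = aft.freqs[("all", locus)]
            for a_idx, lab in enumerate(truth.allele_labels[j]):
                p = truth.pop_freqs[0][j][a_idx]
                se = np.sqrt(p * (1 - p) / 10000)
                assert abs(f.get(lab, 0.0) - p) < 3 * se + 1e-12


class TestHeterozygosity:
    def test_all_homozygotes(self):
        t = single_locus_table([("9", "9"), ("10", "10")])
        df = heterozygosity(t, "all")
        assert df.loc[0, "Ho"] == 0.0

    def test_hand_example(self):
        t = single_locus_table([("9", "10"), ("9", "9")])
        df = heterozygosity(t, "all")
        assert df.loc[0, "Ho"] == pytest.approx(0.5)
        assert df.loc[0, "He"] == pytest.approx((4 / 3) * (1 - 0.625))

    def test_monomorphic_he_zero(self):
        t = single_locus_table([("10", "10")] * 5)
        assert heterozygosity(t, "all").loc[0, "He"] == 0.0

    def test_ho_invariant_to_relabeling(self):
        t1 = single_locus_table([("8", "9"), ("8", "8")])
        t2 = single_locus_table([("11", "12"), ("11", "11")])
        assert (heterozygosity(t1, "all").loc[0, "Ho"]
                == heterozygosity(t2, "all").loc[0, "Ho"])


# ---------------------------------------------------------------------------
# HWE exact tests
# ---------------------------------------------------------------------------

class TestHweExact:
    def test_single_heterozygote_p_one(self):
        t = single_locus_table([("9", "10")])
        res = hwe_exact_test(t, "all", "LOC", population="all",
                             steps=100, dememorization=10, seed=1)
        assert res.p == 1.0

    def test_monomorphic_flagged(self):
        t = single_locus_table([("9", "9")] * 4)
        res = hwe_exact_test(t, "all", "LOC", population="all",
                             steps=100, dememorization=10, seed=1)
        assert not res.applicable

    def test_matches_enumeration_exhaustively(self):
        """MCMC p equals the full-enumeration p on every <=6-copy instance."""
        for genos in all_instances(max_individuals=3, n_alleles=3):
            t = single_locus_table(genos)
            res = hwe_exact_test(t, "all", "LOC", population="all",
                                 steps=100_000, dememorization=5_000, seed=5)
            exact = oracle_p_two_sided(genos)
            se = max(res.se, np.sqrt(exact * (1 - exact) / 100_000), 1e-4)
            assert abs(res.p - exact) <= 3 * se, (genos, res.p, exact)

    def test_reproducible_from_seed(self, rng):
        t = hwe_table(rng, [0.4, 0.3, 0.3], 30)
        r1 = hwe_exact_test(t, "all", "LOC", population="all",
                            steps=5000, dememorization=500, seed=7)
        r2 = hwe_exact_test(t, "all", "LOC", population="all",
                            steps=5000, dememorization=500, seed=7)
        assert r1.p == r2.p


class TestHweDirection:
    def test_extreme_deficiency(self):
        genos = [("8", "8")] * 10 + [("9", "9")] * 10
        t = single_locus_table(genos)
        res = hwe_direction(t, "all", "LOC", "all", steps=20_000,
                            dememorization=2_000, seed=3)
        assert res["direction"] == "deficiency"
        assert res["p_deficiency"] < 0.001

    def test_hwe_proportions_no_direction(self, rng):
        t = hwe_table(rng, [0.5, 0.5], 400)
        res = hwe_direction(t, "all", "LOC", "all", steps=20_000,
                            dememorization=2_000, seed=4)
        assert res["direction"] == "none"

    def test_one_sided_matches_enumeration(self):
        genos = [("8", "8"), ("8", "9"), ("9", "9"), ("8", "9"), ("8", "8")]
        t = single_locus_table(genos)
        res = hwe_direction(t, "all", "LOC", "all", steps=30_000,
                            dememorization=2_000, seed=6)
        for side, key in (("le", "p_deficiency"), ("ge", "p_excess")):
            exact = oracle_p_one_sided(genos, side)
            se = max(res[f"se_{'deficiency' if side == 'le' else 'excess'}"],
                     1e-4)
            assert abs(res[key] - exact) <= 3 * se


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expect", [
        (0.05, 15, 0.00333), (0.05, 1, 0.05), (0.01, 4, 0.0025),
    ])
    def test_values(self, alpha, n, expect):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expect, abs=5e-6)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


# ---------------------------------------------------------------------------
# ML null-allele estimation
# ---------------------------------------------------------------------------

def simulate_null_locus(rng, r, n, k=5):
    """Genotypes at one locus with k equifrequent visible alleles and
    silent-allele frequency r (visible/null -> apparent homozygote,
    null/null -> missing)."""
    labels = [str(8 + i) for i in range(k)]
    p = np.full(k + 1, (1 - r) / k)
    p[-1] = r
    draws = rng.choice(k + 1, size=(n, 2), p=p)
    genos = []
    for a, b in draws:
        if a == k and b == k:
            genos.append((None, None))
        elif a == k:
            genos.append((labels[b], labels[b]))
        elif b == k:
            genos.append((labels[a], labels[a]))
        else:
            genos.append((labels[a], labels[b]))
    return single_locus_table(genos)


class TestNullAlleleML:
    def test_no_signal_gives_small_estimate(self, rng):
        t = simulate_null_locus(rng, r=0.0, n=1000)
        res = null_allele_ml(t, "all", "LOC", "all")
        assert res.null_freq < 0.01

    def test_em_loglik_nondecreasing(self, rng):
        t = simulate_null_locus(rng, r=0.15, n=200)
        lls = [null_allele_ml(t, "all", "LOC", "all", max_iter=m,
                              tol=0.0).loglik
               for m in (1, 2, 5, 20, 100)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_visible_plus_null_sums_to_one(self, rng):
        t = simulate_null_locus(rng, r=0.1, n=500)
        res = null_allele_ml(t, "all", "LOC", "all")
        assert res.converged
        total = sum(res.visible_freqs.values()) + res.null_freq
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_bias_shrinks_with_n(self):
        """EM estimate is consistent: error shrinks as n grows."""
        r = 0.17
        errs = []
        for n in (100, 2000):
            est = []
            for rep in range(8):
                rng = np.random.default_rng(1000 + rep)
                t = simulate_null_locus(rng, r=r, n=n)
                est.append(null_allele_ml(t, "all", "LOC", "all").null_freq)
            errs.append(abs(np.mean(est) - r))
        assert errs[1] < errs[0] + 0.01
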