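"""Differentiation stage: Weir–Cockerham theta, AMOVA, FCA.

Oracles here are coded independently of the package's routes:
theta via the nested-ANOVA mean-squares (MSP/MSI/MSG) formulation, AMOVA
via explicit pairwise copy distance matrices, FCA via a dense
eigendecomposition of the standardized cross-product matrix.
"""

import numpy as np
import pytest

from strpopgen.differentiation import amova, fca, pairwise_fst, weir_cockerham_theta
from strpopgen.simgen import PopulationLabels, SimulationConfig, botswana_preset, simulate
from strpopgen.strdata import Genotype, GenotypeTable, Individual

from conftest import make_random_table

TWO_POPS = [PopulationLabels(phylum="Bantu"), PopulationLabels(phylum="Khoisan")]


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_theta(table, grouping):
    """Weir–Cockerham multilocus theta via nested-ANOVA mean squares."""
    groups = table.group_indices(grouping)
    sum_a = sum_abc = 0.0
    for j, locus in enumerate(table.loci):
        ys = []  # per population: list of allele-copy counts per individual
        for rows in groups.values():
            pop = []
            for i in rows:
                g = table.calls[i][j]
                if not g.missing and not g.triallelic:
                    pop.append(g.alleles)
            ys.append(pop)
        ys = [p for p in ys if p]
        r = len(ys)
        n_i = np.array([len(p) for p in ys], dtype=float)
        N = n_i.sum()
        if r < 2 or N <= r:
            continue
        nc = (N - (n_i**2).sum() / N) / (r - 1)
        alleles = sorted({a for p in ys for g in p for a in g})
        for al in alleles:
            y = [[ (g[0] == al) + (g[1] == al) for g in p] for p in ys]
            p_i = np.array([np.mean(v) / 2 for v in y])
            pbar = sum(np.sum(v) for v in y) / (2 * N)
            ssp = float(np.sum(2 * n_i * (p_i - pbar) ** 2))
            ssi = float(np.sum([np.sum(2 * (np.array(v) / 2 - p_i[k]) ** 2)
                                for k, v in enumerate(y)]))
            ssg = float(np.sum([sum(c * (2 - c) / 2 for c in v) for v in y]))
            msp = ssp / (r - 1)
            msi = ssi / (N - r)
            msg = ssg / N
            a = (msp - msi) / (2 * nc)
            b = (msi - msg) / 2
            c = msg
            sum_a += a
            sum_abc += a + b + c
    return sum_a / sum_abc


def oracle_amova_ss(copy_vectors, membership):
    """Sums of squares from explicit pairwise identity distances.

    ``copy_vectors``: (M, L) allele codes per copy; ``membership``: group
    index per copy.  Returns (ss_total, {group: ss_within}).
    """
    M = len(copy_vectors)
    d2 = np.zeros((M, M))
    for u in range(M):
        for v in range(u + 1, M):
            d2[u, v] = d2[v, u] = np.sum(copy_vectors[u] != copy_vectors[v])
    ss_total = d2[np.triu_indices(M, 1)].sum() / M
    ss_within = {}
    for g in np.unique(membership):
        idx = np.nonzero(membership == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within[g] = sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------

class TestTheta:
    def test_matches_anova_oracle(self, rng):
        t = make_random_table(rng, n_individuals=40, n_loci=4,
                              missing_rate=0.1)
        got = weir_cockerham_theta(t, "phylum")["theta"]
        assert got == pytest.approx(oracle_theta(t, "phylum"), rel=1e-8)

    def test_invariant_to_population_order(self, rng):
        t = make_random_table(rng, n_individuals=30, n_loci=3)
        perm = list(rng.permutation(t.n_individuals))
        assert weir_cockerham_theta(t, "phylum")["theta"] == pytest.approx(
            weir_cockerham_theta(t.subset(perm), "phylum")["theta"])

    def test_fixed_differences_give_theta_one(self):
        inds = [Individual(id=f"a{i}", phylum="Bantu") for i in range(10)]
        inds += [Individual(id=f"b{i}", phylum="Khoisan") for i in range(10)]
        calls = [[Genotype(("8", "8"))] * 3 for _ in range(10)]
        calls += [[Genotype(("12", "12"))] * 3 for _ in range(10)]
        t = GenotypeTable(["L1", "L2", "L3"], inds, calls)
        assert weir_cockerham_theta(t, "phylum")["theta"] == pytest.approx(1.0)


class TestPairwiseFst:
    def test_null_split_not_significant(self, rng):
        cfg = SimulationConfig(n_pops=2, pop_sizes=(60, 60), n_loci=8,
                               alleles_per_locus=6, fst=0.0, seed=21,
                               label_plan=TWO_POPS)
        table, _ = simulate(cfg)
        res = pairwise_fst(table, "phylum", n_perm=200, seed=1)
        assert abs(res.theta[0, 1]) < 0.01
        assert res.p[0, 1] > res.significance_level

    def test_matrix_symmetric_zero_diagonal(self, rng):
        t = make_random_table(rng, n_individuals=40, n_loci=3)
        res = pairwise_fst(t, "phylum", n_perm=50, seed=2)
        assert np.allclose(res.theta, res.theta.T)
        assert np.all(np.diag(res.theta) == 0)
        assert np.all((res.p > 0) & (res.p <= 1))

    def test_recovers_simulated_differentiation(self):
        """Mean theta over replicates matches the Balding–Nichols F."""
        thetas = []
        for seed in range(1, 11):
            cfg = SimulationConfig(n_pops=2, pop_sizes=(500, 500), n_loci=15,
                                   alleles_per_locus=8, fst=0.01213,
                                   seed=seed, label_plan=TWO_POPS)
            table, _ = simulate(cfg)
            thetas.append(weir_cockerham_theta(table, "phylum")["theta"])
        assert np.mean(thetas) == pytest.approx(0.01213, abs=0.004)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def toy_table(rng, n_pops=3, per_pop=4, n_loci=2):
    phy = ["Bantu", "Khoisan"]
    subs = [["Central-K", "Central-R", "Central-S"],
            ["Khoe-Kwadi", "Kx'a", "Tuu"]]
    inds, calls = [], []
    for p in range(n_pops):
        for i in range(per_pop):
            ph = phy[p % 2]
            inds.append(Individual(id=f"p{p}i{i}", phylum=ph,
                                   subgroup=subs[p % 2][p // 2]))
            calls.append([Genotype((str(rng.integers(8, 11)),
                                    str(rng.integers(8, 11))))
                          for _ in range(n_loci)])
    return GenotypeTable([f"L{j}" for j in range(n_loci)], inds, calls)


class TestAmova:
    def test_duplicated_population_no_structure(self, rng):
        t = make_random_table(rng, n_individuals=40, n_loci=4,
                              missing_rate=0, phyla=("Bantu", "Khoisan"))
        res = amova(t, populations="phylum", n_perm=100, seed=1)
        assert abs(res.percentages["among_populations"]) < 2.0
        assert abs(res.f_st) < 0.02

    def test_components_match_distance_oracle(self, rng):
        """Variance components equal the explicit pairwise-distance SS route."""
        t = toy_table(rng, n_pops=3, per_pop=4, n_loci=2)
        res = amova(t, populations="subgroup", n_perm=10, seed=1)
        # oracle: copies as multilocus vectors (no missing data in toy)
        from strpopgen.strdata import encode_calls
        codes, _ = encode_calls(t)
        n = t.n_individuals
        vecs = np.concatenate([codes[:, :, 0], codes[:, :, 1]], axis=0)
        # offset codes per locus so equality compares within-locus only
        member = np.concatenate([np.arange(n), np.arange(n)])
        sub_of = [ind.subgroup for ind in t.individuals]
        pops = sorted(set(sub_of))
        pop_of_copy = np.array([pops.index(sub_of[i]) for i in member])
        ss_total, ss_within = oracle_amova_ss(vecs, pop_of_copy)
        ss_wp = sum(ss_within.values())
        P = len(pops)
        M = 2 * n
        n_p = np.array([np.sum(pop_of_copy == k) for k in range(P)], float)
        ms_wp = ss_wp / (M - P)
        ms_ap = (ss_total - ss_wp) / (P - 1)
        n_prime = (M - (n_p**2).sum() / M) / (P - 1)
        sigma_c = ms_wp
        sigma_b = (ms_ap - ms_wp) / n_prime
        assert res.components["within_populations"] == pytest.approx(
            sigma_c, abs=1e-9)
        assert res.components["among_populations"] == pytest.approx(
            sigma_b, abs=1e-9)

    def test_percentages_sum_to_100(self, rng):
        t = toy_table(rng, n_pops=4, per_pop=5, n_loci=3)
        groups = {"Central-K": "B", "Central-R": "B",
                  "Khoe-Kwadi": "K", "Kx'a": "K"}
        res = amova(t, populations="subgroup", groups=groups,
                    n_perm=20, seed=2)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.01)
        assert res.design == "hierarchical"
        # indices consistent with components
        tot = sum(res.components.values())
        assert res.f_ct == pytest.approx(
            res.components["among_groups"] / tot, abs=1e-12)

    def test_single_group_falls_back(self, rng):
        t = toy_table(rng, n_pops=3, per_pop=4)
        groups = {s: "only" for s in {i.subgroup for i in t.individuals}}
        res = amova(t, populations="subgroup", groups=groups, n_perm=10, seed=3)
        assert res.design == "non-hierarchical"

    def test_ethnolinguistic_beats_random_geography(self):
        """Grouping aligned with the simulated divergence explains more
        variance than an orthogonal district-like partition."""
        cfg = botswana_preset(seed=23)
        cfg.pop_sizes = (188, 60)   # scaled-down sampling design
        table, _ = simulate(cfg)
        res_ethno = amova(table, populations="subgroup", n_perm=10, seed=4)
        res_geo = amova(table, populations="district", n_perm=10, seed=5)
        assert (res_ethno.percentages["among_populations"]
                > res_geo.percentages["among_populations"])


# ---------------------------------------------------------------------------
# FCA
# ---------------------------------------------------------------------------

class TestFca:
    def test_eigenvalues_match_dense_oracle(self, rng):
        t = make_random_table(rng, n_individuals=30, n_loci=4,
                              missing_rate=0.05)
        res = fca(t, "phylum")
        # independent route: eigendecomposition of S^T S
        from strpopgen.differentiation import _one_hot
        X, _, Valid, registries = _one_hot(t)
        cols = []
        for j in range(t.n_loci):
            for a in range(len(registries[j])):
                col = X[:, j, a]
                if 0 < col.sum() < 2 * Valid[:, j].sum():
                    cols.append(col)
        M = np.column_stack(cols)
        M = M[M.sum(axis=1) > 0]
        N = M / M.sum()
        r = N.sum(axis=1)
        c = N.sum(axis=0)
        S = (N - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        evals = np.linalg.eigvalsh(S.T @ S)[::-1]
        evals = evals[evals > 1e-12]
        assert np.allclose(res.eigenvalues, evals[:len(res.eigenvalues)],
                           rtol=1e-8)

    def test_total_inertia_equals_eigenvalue_sum(self, rng):
        t = make_random_table(rng, n_individuals=25, n_loci=3)
        res = fca(t, "phylum")
        assert res.percent_inertia.sum() == pytest.approx(100.0, abs=1e-9)

    def test_exchangeable_populations_no_separation(self):
        cfg = SimulationConfig(n_pops=2, pop_sizes=(80, 80), n_loci=8,
                               alleles_per_locus=6, fst=0.0, seed=31,
                               label_plan=TWO_POPS)
        table, _ = simulate(cfg)
        res = fca(table, "phylum")
        gap = abs(res.centroids.iloc[0, 0] - res.centroids.iloc[1, 0])
        assert gap < np.std(res.coords[:, 0])

    def test_diverged_population_is_extreme_centroid(self):
        plan = [PopulationLabels(phylum="Bantu", subgroup_weights={"Central-K": 1}),
                PopulationLabels(phylum="Bantu", subgroup_weights={"Central-R": 1}),
                PopulationLabels(phylum="Khoisan", subgroup_weights={"Tuu": 1})]
        cfg = SimulationConfig(n_pops=3, pop_sizes=(60, 60, 60), n_loci=10,
                               alleles_per_locus=6, fst=0.02, seed=33,
                               label_plan=plan)
        table, truth = simulate(cfg)
        # make the third population strongly diverged by resimulating it
        # with high F: instead, just relabel after drawing with high fst
        cfg2 = SimulationConfig(n_pops=3, pop_sizes=(60, 60, 60), n_loci=10,
                                alleles_per_locus=6, fst=0.25, seed=33,
                                label_plan=plan)
        table2, truth2 = simulate(cfg2)
        # mix: first two populations from low-F draw, third from high-F draw
        rows = list(range(120)) + list(range(120, 180))
        mixed = GenotypeTable(
            table.loci,
            [table.individuals[i] if i < 120 else table2.individuals[i]
             for i in rows],
            [table.calls[i] if i < 120 else table2.calls[i] for i in rows],
        )
        res = fca(mixed, "subgroup")
        ax1 = res.centroids["axis1"]
        assert ax1.idxmax() == "Tuu" or ax1.idxmin() == "Tuu"
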