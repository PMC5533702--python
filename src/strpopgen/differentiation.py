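"""Population differentiation: Weir–Cockerham FST, AMOVA, and factorial
correspondence analysis.

FST uses the Weir–Cockerham (1984) moment estimator theta: per locus and
allele, variance components a (among populations), b (among individuals
within populations) and c (within individuals) are computed from sample
sizes, allele frequencies and heterozygote frequencies, and the multilocus
estimate is the ratio of summed components sum(a) / sum(a + b + c).
Negative estimates are reported as computed (not truncated), since
truncation would bias the permutation null.

AMOVA partitions the total variance of allele copies with the identity
("FST-like", number-of-different-alleles) distance: the squared distance
between two copies is the number of loci at which their alleles differ.
The within-individual stratum is collapsed into within-populations, giving
the three-level presentation (among groups / among populations within
groups / within populations) and the fixation indices F_ST, F_SC, F_CT.

FCA is correspondence analysis of the individuals x alleles count matrix
(entries 0/1/2): chi-square standardization of the relative-frequency
matrix, SVD, principal coordinates for individuals, and population
centroids as member means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strdata import GenotypeTable, encode_calls

__all__ = [
    "FstMatrix",
    "AmovaResult",
    "FcaResult",
    "weir_cockerham_theta",
    "pairwise_fst",
    "amova",
    "fca",
]


# ---------------------------------------------------------------------------
# Encodings shared by the numeric routines
# ---------------------------------------------------------------------------

def _one_hot(table: GenotypeTable):
    """(X, Het, Valid): per-individual allele-copy counts, per-allele
    heterozygote indicators, and non-missing flags, padded over loci."""
    codes, registries = encode_calls(table)
    n, L, _ = codes.shape
    amax = max((len(r) for r in registries), default=1)
    X = np.zeros((n, L, amax), dtype=np.float64)
    Het = np.zeros((n, L, amax), dtype=np.float64)
    valid = codes[:, :, 0] >= 0
    ii, jj = np.nonzero(valid)
    a0 = codes[ii, jj, 0]
    a1 = codes[ii, jj, 1]
    np.add.at(X, (ii, jj, a0), 1.0)
    np.add.at(X, (ii, jj, a1), 1.0)
    het = a0 != a1
    np.add.at(Het, (ii[het], jj[het], a0[het]), 1.0)
    np.add.at(Het, (ii[het], jj[het], a1[het]), 1.0)
    return X, Het, valid.astype(np.float64), registries


def _wc_sums(X, Het, Valid, masks):
    """Per-population sums needed by the theta estimator.

    ``masks``: list of boolean arrays over individuals.  Returns arrays of
    shape (r, L) sample sizes, (r, L, A) allele counts and heterozygote
    counts.
    """
    n_i = np.stack([Valid[m].sum(axis=0) for m in masks])          # (r, L)
    S = np.stack([X[m].sum(axis=0) for m in masks])                # (r, L, A)
    H = np.stack([Het[m].sum(axis=0) for m in masks])              # (r, L, A)
    return n_i, S, H


def _theta_components(n_i, S, H):
    """Weir–Cockerham a, b, c summed over alleles, per locus.

    Input shapes: n_i (..., r, L); S, H (..., r, L, A).  Loci where fewer
    than two populations have data, or n_bar <= 1, contribute NaN.
    """
    r = n_i.shape[-2]
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = n_i.sum(axis=-2)                                   # (L,)
        n_bar = n_sum / r
        nc = (n_sum - (n_i**2).sum(axis=-2) / n_sum) / (r - 1)
        p_i = S / (2.0 * n_i[..., None])                           # (r, L, A)
        p_bar = S.sum(axis=-3) / (2.0 * n_sum[..., None])          # (L, A)
        h_bar = H.sum(axis=-3) / n_sum[..., None]
        dev = p_i - p_bar[..., None, :, :]
        s2 = (n_i[..., None] * dev**2).sum(axis=-3) / ((r - 1) * n_bar[..., None])
        pq = p_bar * (1.0 - p_bar)
        nb = n_bar[..., None]
        ncc = nc[..., None]
        a = (nb / ncc) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (nb - 1.0))
        b = (nb / (nb - 1.0)) * (pq - (r - 1) / r * s2
                                 - (2.0 * nb - 1.0) / (4.0 * nb) * h_bar)
        c = h_bar / 2.0
        usable = ((n_i > 0).sum(axis=-2) >= 2) & (n_bar > 1.0) & (nc > 0)
    a = np.where(usable[..., None], a, np.nan).sum(axis=-1)
    b = np.where(usable[..., None], b, np.nan).sum(axis=-1)
    c = np.where(usable[..., None], c, np.nan).sum(axis=-1)
    return a, b, c   # per locus (NaN where unusable)


def weir_cockerham_theta(table: GenotypeTable, grouping: str = "phylum"):
    """Multilocus and per-locus Weir–Cockerham theta over the groups.

    Returns a dict with 'theta' (multilocus), 'per_locus' (Series indexed
    by locus) and 'populations'.
    """
    groups = table.group_indices(grouping)
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    X, Het, Valid, _ = _one_hot(table)
    masks = []
    for rows in groups.values():
        m = np.zeros(table.n_individuals, dtype=bool)
        m[rows] = True
        masks.append(m)
    n_i, S, H = _wc_sums(X, Het, Valid, masks)
    a, b, c = _theta_components(n_i, S, H)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / (a + b + c)
        theta = np.nansum(a) / np.nansum(a + b + c)
    return {
        "theta": float(theta),
        "per_locus": pd.Series(per_locus, index=table.loci),
        "populations": list(groups),
    }


# ---------------------------------------------------------------------------
# Pairwise FST with permutation p-values
# ---------------------------------------------------------------------------

@dataclass
class FstMatrix:
    populations: list[str]
    theta: np.ndarray
    p: np.ndarray
    n_permutations: int
    significance_level: float
    bonferroni_level: float

    def significant(self, i: int, j: int) -> bool:
        return self.p[i, j] < self.bonferroni_level

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.populations,
                            columns=self.populations)


def _pair_theta_perms(X, Het, Valid, rows_a, rows_b, n_perm, rng):
    """Observed multilocus theta for one pair plus its permutation null.

    Permutes individuals between the two populations (sizes preserved)
    with a batched one-hot matmul so the whole null is a few BLAS calls.
    """
    idx = np.concatenate([rows_a, rows_b])
    na = len(rows_a)
    Xp = X[idx]
    Hp = Het[idx]
    Vp = Valid[idx]
    n, L, A = Xp.shape

    def theta_from_mask(Mrow):
        # Mrow: (P, n) 0/1 membership of population a
        n1 = Mrow @ Vp                                   # (P, L)
        S1 = (Mrow @ Xp.reshape(n, -1)).reshape(-1, L, A)
        H1 = (Mrow @ Hp.reshape(n, -1)).reshape(-1, L, A)
        n_tot = Vp.sum(axis=0)
        S_tot = Xp.sum(axis=0)
        H_tot = Hp.sum(axis=0)
        n_i = np.stack([n1, n_tot - n1], axis=1)         # (P, 2, L)
        S = np.stack([S1, S_tot - S1], axis=1)           # (P, 2, L, A)
        H = np.stack([H1, H_tot - H1], axis=1)
        a, b, c = _theta_components(n_i, S, H)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nansum(a, axis=-1) / np.nansum(a + b + c, axis=-1)

    obs_mask = np.zeros((1, n))
    obs_mask[0, :na] = 1.0
    theta_obs = float(theta_from_mask(obs_mask)[0])

    exceed = 0
    chunk = 512
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        M = np.zeros((m, n))
        for t in range(m):
            M[t, rng.permutation(n)[:na]] = 1.0
        th = theta_from_mask(M)
        exceed += int(np.sum(th >= theta_obs - 1e-12))
        done += m
    p = (1 + exceed) / (n_perm + 1)
    return theta_obs, p


def pairwise_fst(
    table: GenotypeTable,
    grouping: str = "phylum",
    n_perm: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
) -> FstMatrix:
    """All pairwise multilocus theta values with permutation p-values.

    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1), permuting
    individuals between the two populations; the significance level is
    Bonferroni-adjusted over the number of pairs.
    """
    groups = table.group_indices(grouping)
    pops = [p for p, rows in groups.items() if len(rows) >= 2]
    if len(pops) < 2:
        raise ValueError("need >= 2 populations with >= 2 individuals")
    X, Het, Valid, _ = _one_hot(table)
    r = len(pops)
    theta = np.zeros((r, r))
    pmat = np.ones((r, r))
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(r), 2):
        th, p = _pair_theta_perms(
            X, Het, Valid,
            np.asarray(groups[pops[i]]), np.asarray(groups[pops[j]]),
            n_perm, rng,
        )
        theta[i, j] = theta[j, i] = th
        pmat[i, j] = pmat[j, i] = p
    n_pairs = r * (r - 1) // 2
    return FstMatrix(
        populations=pops, theta=theta, p=pmat, n_permutations=n_perm,
        significance_level=alpha, bonferroni_level=alpha / n_pairs,
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    design: str                       # 'non-hierarchical' | 'hierarchical'
    components: dict[str, float]      # sigma2 by stratum
    percentages: dict[str, float]
    f_st: float
    f_sc: float | None
    f_ct: float | None
    p_values: dict[str, float]
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"source": k, "variance": v, "percent": self.percentages[k]}
            for k, v in self.components.items()
        ]
        return pd.DataFrame(rows)


def _ss_within(counts: np.ndarray, n_copies: np.ndarray) -> np.ndarray:
    """Per-locus SS of a copy set under identity distance.

    ``counts``: (L, A) allele-copy counts; ``n_copies``: (L,).
    SS = [C(n,2) - sum_a C(m_a,2)] / n.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        pairs_all = n_copies * (n_copies - 1) / 2.0
        pairs_same = (counts * (counts - 1) / 2.0).sum(axis=-1)
        ss = (pairs_all - pairs_same) / n_copies
    return np.where(n_copies > 0, ss, 0.0)


def _amova_components(S_pops, N_pops, group_of_pop):
    """Variance components for one partition, summed over loci.

    ``S_pops``: (P, L, A) allele-copy counts per population; ``N_pops``:
    (P, L) copy counts; ``group_of_pop``: array of group index per
    population (all zeros -> non-hierarchical).  Returns
    (sigma_a, sigma_b, sigma_c) where sigma_a is None for the
    non-hierarchical design (two strata only).
    """
    P, L, A = S_pops.shape
    groups = np.unique(group_of_pop)
    G = len(groups)
    S_tot = S_pops.sum(axis=0)
    N_tot = N_pops.sum(axis=0)

    ss_wp = _ss_within(
        S_pops.reshape(-1, A), N_pops.reshape(-1)
    ).reshape(P, L).sum(axis=0)
    ss_total = _ss_within(S_tot, N_tot)

    sigma_a_sum = sigma_b_sum = sigma_c_sum = 0.0
    for l in range(L):
        n_p = N_pops[:, l]
        used = n_p > 0
        Pl = int(used.sum())
        if Pl < 2:
            continue
        N = n_p.sum()
        df_wp = N - Pl
        if df_wp <= 0:
            continue
        ms_wp = ss_wp[l] / df_wp
        if G == 1:
            df_ap = Pl - 1
            ss_ap = ss_total[l] - ss_wp[l]
            ms_ap = ss_ap / df_ap
            n_prime = (N - (n_p**2).sum() / N) / (Pl - 1)
            sigma_c = ms_wp
            sigma_b = (ms_ap - ms_wp) / n_prime
            sigma_b_sum += sigma_b
            sigma_c_sum += sigma_c
        else:
            # hierarchical: groups / populations-within-groups / within
            gl = group_of_pop
            Ng = np.array([n_p[gl == g].sum() for g in groups])
            used_g = Ng > 0
            Gl = int(used_g.sum())
            ss_g = np.zeros(len(groups))
            for gi, g in enumerate(groups):
                sel = gl == g
                ss_g[gi] = _ss_within(
                    S_pops[sel, l].sum(axis=0)[None, :], np.array([Ng[gi]])
                )[0]
            ss_ag = ss_total[l] - ss_g.sum()
            ss_apwg = ss_g.sum() - ss_wp[l]
            df_ag = Gl - 1
            df_apwg = Pl - Gl
            if df_ag <= 0 or df_apwg <= 0:
                continue
            ms_ag = ss_ag / df_ag
            ms_apwg = ss_apwg / df_apwg
            sum_np2_over_ng = sum(
                (n_p[gl == g]**2).sum() / Ng[gi]
                for gi, g in enumerate(groups) if Ng[gi] > 0
            )
            n_coef = (N - sum_np2_over_ng) / df_apwg
            n_prime = (sum_np2_over_ng - (n_p**2).sum() / N) / df_ag
            n_dprime = (N - (Ng[used_g]**2).sum() / N) / df_ag
            sigma_c = ms_wp
            sigma_b = (ms_apwg - sigma_c) / n_coef
            sigma_a = (ms_ag - sigma_c - n_prime * sigma_b) / n_dprime
            sigma_a_sum += sigma_a
            sigma_b_sum += sigma_b
            sigma_c_sum += sigma_c
    if G == 1:
        return None, sigma_b_sum, sigma_c_sum
    return sigma_a_sum, sigma_b_sum, sigma_c_sum


def amova(
    table: GenotypeTable,
    populations: str = "subgroup",
    groups: dict[str, str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Analysis of molecular variance over a population partition.

    ``populations`` names the metadata field defining populations;
    ``groups`` optionally maps each population label to a group label
    (hierarchical design).  Each individual contributes two allele copies
    per locus; the squared inter-copy distance is the number of loci at
    which the alleles differ.  Permutation p-values: individuals among
    populations for the within/among-population components, whole
    populations among groups for F_CT.
    """
    pop_groups = table.group_indices(populations)
    pops = list(pop_groups)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if groups is not None:
        missing = [p for p in pops if p not in groups]
        if missing:
            raise ValueError(f"populations without a group: {missing}")
        glabels = sorted({groups[p] for p in pops})
        if len(glabels) < 2:
            design = "non-hierarchical"
            group_of_pop = np.zeros(len(pops), dtype=int)
        else:
            design = "hierarchical"
            group_of_pop = np.array([glabels.index(groups[p]) for p in pops])
    else:
        design = "non-hierarchical"
        group_of_pop = np.zeros(len(pops), dtype=int)

    X, Het, Valid, _ = _one_hot(table)
    pop_of_ind = np.full(table.n_individuals, -1, dtype=int)
    for pi, p in enumerate(pops):
        pop_of_ind[pop_groups[p]] = pi
    keep = pop_of_ind >= 0

    def components_for(pop_assign, grp_of_pop):
        S_pops = np.stack([X[keep][pop_assign == pi].sum(axis=0)
                           for pi in range(len(pops))])
        N_pops = np.stack([2.0 * Valid[keep][pop_assign == pi].sum(axis=0)
                           for pi in range(len(pops))])
        return _amova_components(S_pops, N_pops, grp_of_pop)

    assign = pop_of_ind[keep]
    sa, sb, sc = components_for(assign, group_of_pop)
    rng = np.random.default_rng(seed)

    p_values: dict[str, float] = {}
    if design == "non-hierarchical":
        total = sb + sc
        f_st = sb / total
        components = {"among_populations": sb, "within_populations": sc}
        percentages = {k: 100.0 * v / total for k, v in components.items()}
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(assign)
            _, sb_p, sc_p = components_for(perm, group_of_pop)
            if sb_p / (sb_p + sc_p) >= f_st - 1e-12:
                exceed += 1
        p_values["F_ST"] = (1 + exceed) / (n_perm + 1)
        return AmovaResult(design, components, percentages, float(f_st),
                           None, None, p_values, n_perm)

    total = sa + sb + sc
    f_ct = sa / total
    f_sc = sb / (sb + sc)
    f_st = (sa + sb) / total
    components = {
        "among_groups": sa,
        "among_populations_within_groups": sb,
        "within_populations": sc,
    }
    percentages = {k: 100.0 * v / total for k, v in components.items()}

    exceed_st = exceed_sc = 0
    for _ in range(n_perm):
        perm = rng.permutation(assign)
        sa_p, sb_p, sc_p = components_for(perm, group_of_pop)
        tot_p = sa_p + sb_p + sc_p
        if (sa_p + sb_p) / tot_p >= f_st - 1e-12:
            exceed_st += 1
        if sb_p / (sb_p + sc_p) >= f_sc - 1e-12:
            exceed_sc += 1
    exceed_ct = 0
    for _ in range(n_perm):
        gperm = rng.permutation(group_of_pop)
        sa_p, sb_p, sc_p = components_for(assign, gperm)
        if sa_p / (sa_p + sb_p + sc_p) >= f_ct - 1e-12:
            exceed_ct += 1
    p_values["F_ST"] = (1 + exceed_st) / (n_perm + 1)
    p_values["F_SC"] = (1 + exceed_sc) / (n_perm + 1)
    p_values["F_CT"] = (1 + exceed_ct) / (n_perm + 1)
    return AmovaResult(design, components, percentages, float(f_st),
                       float(f_sc), float(f_ct), p_values, n_perm)


# ---------------------------------------------------------------------------
# Factorial correspondence analysis
# ---------------------------------------------------------------------------

@dataclass
class FcaResult:
    eigenvalues: np.ndarray
    percent_inertia: np.ndarray
    coords: np.ndarray                # individuals x axes (principal)
    individual_ids: list[str]
    populations: list[str]            # per individual
    centroids: pd.DataFrame           # population x axes
    column_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"axis{k + 1}" for k in range(self.coords.shape[1])],
        )
        df.insert(0, "id", self.individual_ids)
        df.insert(1, "population", self.populations)
        return df


def fca(table: GenotypeTable, grouping: str = "phylum", n_axes: int = 5) -> FcaResult:
    """Correspondence analysis of the individuals x alleles count matrix.

    Monomorphic (constant) allele columns are dropped before the
    decomposition; individuals with no scored genotype at all are dropped.
    Axis signs are fixed by forcing the largest-|coordinate| entry of each
    axis positive.
    """
    X, _, Valid, registries = _one_hot(table)
    n, L, A = X.shape
    cols = []
    labels = []
    for j in range(L):
        for a in range(len(registries[j])):
            col = X[:, j, a]
            if 0 < col.sum() < 2 * Valid[:, j].sum():   # polymorphic only
                cols.append(col)
                labels.append(f"{table.loci[j]}:{registries[j][a]}")
    M = np.column_stack(cols) if cols else np.zeros((n, 0))
    if M.shape[1] < 2:
        raise ValueError("need >= 2 polymorphic allele columns")
    row_ok = M.sum(axis=1) > 0
    M = M[row_ok]
    ids = [ind.id for ind, ok in zip(table.individuals, row_ok) if ok]
    pops = [v for v, ok in zip(table.metadata_values(grouping), row_ok) if ok]

    Nrel = M / M.sum()
    r = Nrel.sum(axis=1)
    c = Nrel.sum(axis=0)
    S = (Nrel - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    lam = s**2
    pos = lam > 1e-12
    lam = lam[pos]
    U = U[:, pos]
    s = s[pos]
    k = min(n_axes, len(lam))
    F = (U[:, :k] * s[:k]) / np.sqrt(r)[:, None]
    for ax in range(k):
        imax = np.argmax(np.abs(F[:, ax]))
        if F[imax, ax] < 0:
            F[:, ax] = -F[:, ax]
    cent = pd.DataFrame(F).groupby(pd.Series(pops)).mean()
    cent.columns = [f"axis{i + 1}" for i in range(k)]
    return FcaResult(
        eigenvalues=lam,
        percent_inertia=100.0 * lam / lam.sum(),
        coords=F,
        individual_ids=ids,
        populations=pops,
        centroids=cent,
        column_labels=labels,
    )
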