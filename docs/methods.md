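# Methods

This note records the models, estimators and numerical choices behind
`strpopgen`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the known limitations.

## Data model

Genotypes are unordered diploid pairs of repeat-count labels; labels are
decimal text with at most one fractional digit ("9.3") and compare
numerically. Missing calls are all-or-nothing per locus. Tri-allelic
patterns (a third amplified allele, observed in real panels at TPOX) are
carried as genotype metadata, surfaced by QC, and **excluded from every
statistic**: all downstream formulas assume diploidy, and including a
third allele would bias frequency, heterozygosity and likelihood
computations in unquantified ways. Missing data are handled by per-locus
pairwise deletion, matching the behaviour of the standard diversity
software for these panels. The sex marker is metadata only.

Genepop I/O encodes microvariant labels as three-digit codes
`round(label × 10)` ("9.3" → 093), a bijection standard in forensic
practice; the STRUCTURE writer recodes alleles to consecutive integers
per locus with a persisted map, missing = −9.

## Synthetic generator

Ancestral frequencies per locus are symmetric-Dirichlet(1); population
frequencies follow the Balding–Nichols draw
`Dirichlet(p_anc (1−F)/F)`, whose expected Wright fixation index is
exactly F — this is what lets differentiation be calibrated to a target
FST analytically (F = 0 copies the ancestral vector; no division by
zero). With admixture enabled, each individual draws
`q ~ Dirichlet(α·1_K)` and each allele copy picks its source population
from q; the largest component of q is aligned with the individual's
labelled population so that labels remain majority ancestry, and the
α → 0 limit degenerates to discrete membership. Silent alleles replace
each transmitted copy independently with probability `null_rate`;
a visible/null pair is recorded as an apparent homozygote and null/null
as a missing call — exactly the observable signature the EM estimator
models. Microvariant labels are cosmetic (a random subset of allele
indices gets a ".3" designation) and exist to exercise I/O.

The study preset uses 752 + 238 individuals, the 15 Identifiler
autosomal loci with 8 alleles per locus, F = 0.01213 (the reported
overall two-phylum differentiation), admixture α = 0.25 (a U-shaped
ancestry distribution: most individuals nearly pure, a substantial
admixed minority, qualitatively matching the study population), a 10%
microvariant fraction, and district labels concentrating the simulated
Khoisan in the Ghanzi and North-west districts.

What the generator does **not** emulate: mutation processes and allele
size constraints, linkage (the panel's loci are unlinked by design),
genotyping error and allelic drop-out other than the null-allele
mechanism, family structure, and real district-level allele-frequency
clines. Passing recovery tests therefore demonstrates estimator
correctness under the stated generative model, not performance on any
particular real population.

## Diversity stage

He uses the unbiased correction `(2n/(2n−1))(1 − Σp̂²)`; cells with a
single individual are flagged rather than given a value.

The Hardy–Weinberg test is the conditional exact test. Its null — all
pairings of the observed allele copies into genotypes equally likely —
is sampled by a Markov chain on the copy arrangement: a step proposes
swapping two uniformly chosen copies in different individuals and always
accepts (a symmetric proposal whose stationary distribution is uniform
over arrangements, which induces the standard conditional distribution
`P ∝ 2^h / Π n_ij!` on genotype tables). The p-value counts visited
states with conditional probability ≤ the observed one, ties included
(tolerance 1e-9 on the log scale). Defaults are the published protocol
(10⁶ steps after 10⁶ dememorization steps); tests and examples use
10⁴/10⁴. The Monte-Carlo standard error is estimated by batch means
(20 batches) to account for chain autocorrelation. One-sided
deficiency/excess tests use the heterozygote count as the statistic
against the same null and are reported as a direction only when the
one-sided p falls below the Bonferroni level — the same level as the
global test, since no separate rule is standard. Monomorphic cells are
flagged not-applicable, never silently p = 1; a single heterozygote is
the lone reachable state and gets p = 1 exactly.

The null-allele estimator maximizes the multinomial class likelihood
(heterozygote `2pᵢpⱼ`, apparent homozygote `pᵢ² + 2pᵢr`, missing `r²`)
by EM; convergence when the log-likelihood gain drops below 1e-8 or
10⁴ iterations, the last iterate flagged if unconverged. Genotyping
failure is not modelled separately from null/null, so `r` is an upper
bound when true missingness exists.

## Forensic stage

*h* and *H* are genotype **relative frequencies**, not raw counts: with
counts the printed formulas leave [0, 1]. MP uses observed
genotype-class frequencies by default (`expected=True` switches to
Hardy–Weinberg expected classes); which the original tooling used is
ambiguous, so both are provided. A locus with no homozygotes has PE = 1
(hence CPE = 1) and an infinite TPI, returned as `math.inf` rather than
an exception. Combined values are reported at full precision.

## Differentiation stage

Pairwise FST is the Weir–Cockerham moment estimator: per-allele variance
components a, b, c from sample sizes, allele frequencies and
heterozygote frequencies; multilocus θ is the ratio of summed components.
Negative estimates are reported as computed — truncation at zero would
bias the permutation null. p-values use the add-one estimator
`(1 + #{θ* ≥ θ}) / (n_perm + 1)`, so p is never exactly zero (a reported
"0.00000" is represented as p < 1/(n_perm+1)); individuals are permuted
between the two populations with sizes preserved, and the significance
level is Bonferroni-adjusted over pairs (default 0.01, 10,000
permutations).

AMOVA uses the identity (number-of-different-alleles) distance between
allele copies, additive over loci; sums of squares come from allele
counts per stratum, and variance components from the standard
unequal-size coefficient formulas. The within-individual stratum is
collapsed into within-populations, giving the three-level presentation;
percentages are components over their total. Permutations: whole
individuals among populations (F_ST, F_SC), whole populations among
groups (F_CT). Repeat-count (R_ST-like) distances are out of scope.

FCA is plain correspondence analysis of the individuals × alleles count
matrix (0/1/2): chi-square standardization of the relative-frequency
matrix, SVD, principal row coordinates, population centroids as member
means. Constant columns (monomorphic alleles) are dropped; axis signs
are fixed by forcing the largest-|coordinate| entry positive.

## Admixture stage

The sampler implements the admixture model with **uncorrelated**
frequencies (Dirichlet λ = 1 prior per cluster × locus). The correlated
F-model was deliberately not implemented: it is substantially more
complex and the uncorrelated model is adequate for the recovery tests
this package makes; at very weak differentiation the correlated prior
extracts somewhat more signal, which is a known gap. α is updated by a
Metropolis random walk (SD 0.05) under a uniform(0, 10) prior. The
model likelihood reported per run is `mean(logL) − var(logL)/2` over
retained sweeps, with `logL = Σ log Σ_k q_ik p_k(allele)` — the
estimator conventionally reported by clustering software. Default chain
lengths are the published protocol (10⁶ burn-in, 10⁵ sweeps, K = 1..6 ×
10 replicates); tests and examples use desk-scale chains (hundreds to
thousands of sweeps), which the separable-data recovery tests show are
sufficient at strong differentiation. Evanno ΔK is defined only at
interior K with positive replicate SD; ties select the smaller K
(parsimony). Replicate alignment is a greedy column-correlation match
to the first replicate — a deliberate simplification of full
label-alignment search; degenerate (constant) columns are matched last.

A note on attainable accuracy: at the preset's F = 0.01213 over 15 loci
the expected total log-likelihood ratio between individuals pure for
either population is only ≈ 1.8 nats (sum of per-locus KL divergences),
so individual-level ancestry estimates are intrinsically diffuse at this
differentiation no matter the chain length; group-level separation is
recoverable, per-individual ancestry only weakly. The package's tests
assert exactly that.

## Assignment stage

Baselines are trained on the non-admixed groups only. Unseen-allele
smoothing gives every allele observed anywhere in the table but absent
from a baseline population frequency `1/(2n+1)` before renormalization;
without it a single private allele forces an infinite likelihood ratio.
The LR is best minus second-best log₁₀ likelihood (for K = 2 this is
the between-phylum ratio); the threshold log₁₀ 3 = 0.477 is boundary
**inclusive**. I_n uses natural logs (its 0-to-ln K range is a
natural-log identity); assignment uses log₁₀ — each convention follows
the method it implements. No leave-one-out correction is applied to
baselines, so accuracy on training individuals is slightly optimistic.

## Pipeline

A single global seed is fanned out per stage through
`SeedSequence([seed, stage_index])`, making stages individually
reproducible and whole runs byte-identical. `RunConfig` defaults are
the published protocol settings; `RunConfig.desk_scale()` (used by the
CLI unless `--full` is passed) reduces chains to 10⁴/10⁴ HWE steps, 200
permutations, and 10³/2×10³-sweep clustering over K = 1..4 × 2, which
completes in minutes on one CPU.

## Problem sizes used in validation

Recovery checks run at: FST — 25 replicates of 2 × 500 individuals, 15
loci × 8 alleles; null alleles — 50 replicates of n = 1000 at one locus
with 5 visible alleles; HWE exactness — every genotype array with ≤ 6
gene copies against full enumeration, and 200 null replicates of
n = 500 for uniformity; admixture — separable populations of 30 + 30 at
10 loci. These sizes give Monte-Carlo error comfortably inside the
tolerances asserted while keeping the whole suite fast.

## Known limitations

- No correlated-frequencies admixture prior, no spatial (CAR) model,
  no kriged admixture surfaces.
- Full label-alignment search (CLUMPP-style) replaced by greedy
  matching.
- MP from observed classes assumes the sample is large enough that
  class frequencies are stable; for very small cells the HWE-expected
  variant is preferable.
- The null-allele model attributes all missingness at a locus to
  null/null pairs.
- No linkage-disequilibrium testing and no kinship LRs beyond TPI.
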