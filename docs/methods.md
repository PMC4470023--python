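# Methods

## Data model

Genotypes are diploid, co-dominant and multi-allelic; allele codes are
opaque positive integers with no repeat-length semantics, since every
statistic in the package is identity-based. A call is either fully typed
or fully missing; a half-typed call (one allele 0) is demoted to missing
with a warning, because no downstream statistic can use it. All per-locus
computations are complete-case: an individual missing at a locus simply
drops out of that locus's sample for its breed.

GenePop (2- or 3-digit) is the exchange format. GenePop has no canonical
population-name field, so a pop block is named by the label of its last
individual — the common convention — overridable by an explicit name list.

## Diversity summaries

Per breed and locus, with `n` typed individuals and allele frequencies
`p_k`:

* unbiased expected heterozygosity `He = 2n/(2n-1) (1 - Σ p_k²)`;
* observed heterozygosity `Ho` = fraction of typed individuals
  heterozygous;
* effective number of alleles `Ae = 1/Σ p_k²`;
* allelic richness by rarefaction,
  `Ar(g) = Σ_k [1 - C(2N - N_k, g)/C(2N, g)]`, the expected number of
  distinct alleles in a subsample of `g` allele copies (computed through
  log-gamma for stability; exact against brute-force enumeration).

Breed values are arithmetic means over loci with at least one typed
individual. `Ae` is averaged arithmetically over loci (the "effective
number of alleles per locus" convention). For richness comparisons,
breeds with any locus typed in fewer than `min_n` individuals (default
18) are excluded and `g` defaults to the smallest `2N` among included
cells, so every included cell is rarefied to a common size.

## F-statistics

The Weir–Cockerham (1984) variance components `a` (among populations),
`b` (among individuals within populations) and `c` (within individuals)
are computed per locus and allele with the weighted, `n_c`-corrected
formulas, then pooled as ratios of sums over alleles and loci:
`F_ST = Σa/Σ(a+b+c)`, `F_IS = 1 - Σc/Σ(b+c)`, `F_IT = 1 - Σc/Σ(a+b+c)`.
Ratios of sums (never means of per-locus ratios) keep rare-allele loci
from destabilizing the estimate; negative components and negative
estimates are reported as-is. The identity
`(1 - F_IT) = (1 - F_IS)(1 - F_ST)` holds exactly through the shared
components and is asserted in the tests. Per-breed `F_IS` applies the
within-population components (`b`, `c`) to that breed alone; pairwise θ
restricts the estimator to each breed pair.

## Distances and the diversity partition

Coancestry `f_ij = Σ_k p_ki p_kj` is averaged over loci
pairwise-complete: a locus undefined in either breed is dropped for that
pair only, and a pair with no shared defined locus propagates NaN — the
partition then fails loudly naming the pair, rather than silently
dropping breeds, because the leave-one-out contributions need a complete
matrix.

Nei's minimum distance is `D_ij = (f_ii + f_jj)/2 - f_ij` (non-negative
by Cauchy–Schwarz, clamped against −1e-12 rounding). The Reynolds
distance pools loci before the ratio,
`D_R = Σ_l Σ_k (p_ki - p_kj)² / [2 Σ_l (1 - Σ_k p_ki p_kj)]`, matching
the PHYLIP convention; the `-ln(1 - D_R)` transform is available behind a
flag but off by default since surveys report `D_R` itself. Two breeds
fixed for the same allele everywhere get distance 0 by convention.

The partition (`GD_T`, `GD_WS`, `GD_BS`) follows the equations in the
README; computing `GD_BS` through Nei's minimum distance makes the
additivity `GD_T = GD_WS + GD_BS` an algebraic identity, which the tests
assert to 1e-12 on randomized matrices. Leave-one-out contributions
recompute the partition on the `(n-1)`-breed submatrix with `n-1` in all
denominators (the breed is genuinely removed from the set, not
re-weighted); the sign convention is after-minus-before, so negative
`ΔGD_T` means the removal loses diversity. Output tables scale the deltas
by 1000 for readability; internal storage is unscaled.

## AMOVA

Three strata: among groups, among breeds within groups, within breeds.
Allele copies are the units with 0/1 identity distance; the
within-individual level is pooled into the within-breed stratum, matching
the three-component table this analysis style reports. Sums of squared
deviations reduce to `SSD = (N² - Σ c_k²)/(2N)` for a set of `N` copies
with allele counts `c_k`. Variance components are solved per locus from
the moment equations with unequal-size coefficients and summed over loci;
F-statistics come from the summed components. Negative components are
reported raw and truncated to zero for the percentage display (renormalized
to 100).

Permutation significance uses three schemes — individuals among breeds
across the whole set (`F_ST`), individuals among breeds within their
group (`F_SC`), whole breeds among groups (`F_CT`) — with
`p = (b + 1)/(m + 1)`. Individuals (intact genotypes), not allele copies,
are permuted. The default 16 000 permutations reproduces the classical
setting; the drivers and tests use 999–1999 for speed. A grouped design
requires every group to hold at least two breeds (callers exclude
singleton-group breeds first); the fully degenerate each-breed-its-own-
group design is allowed and collapses to the two-level analysis.

## Permutation tests and multiple testing

The Hardy–Weinberg test shuffles a breed's allele copies at one locus and
re-pairs them; the statistic is the within-population Weir–Cockerham `f`.
Both one-sided p-values (deficit: `f` at least as large; excess: at least
as small) are reported so either direction convention can be
reconstructed. The test is slightly conservative at small samples because
the permutation distribution of `f` is discrete. Genic differentiation
between two breeds uses the log-likelihood-ratio G statistic on the
2 × alleles count table per locus, permuting intact individuals between
the breeds, and combines loci by Fisher's method. The sequential
Bonferroni correction is Holm's step-down (delegated to statsmodels),
with monotone adjusted p-values capped at 1. All permutation p-values use
`(b + 1)/(m + 1)` and so are never zero.

## Null-allele EM

Genotype classes under random mating with a null allele of frequency `r`:
visible heterozygote `(k, l)` with probability `2 q_k q_l`, apparent
homozygote `k` with `q_k² + 2 q_k r`, blank with `r²`. The EM iterates
expected allele-copy counts until the log-likelihood changes by less than
1e-8 (cap 1000 iterations); cells with `r̂ > 0.2` are flagged but never
auto-dropped — screening is a report, not a filter. Blanks are modelled
as null homozygotes, so ordinary missingness (failed reactions unrelated
to nulls) inflates `r̂`; with the simulator's 2% missing rate a small
number of false flags is expected, which is the familiar behaviour of
this estimator family. An all-blank cell converges to the `r = 1`
boundary and is reported unconverged.

## Clustering post-processing

Runs of a model-based clustering program are identified only up to a
permutation of cluster labels. The symmetric similarity coefficient
between runs is `SSC = max_P 1 - ||Q_a - Q_b P||_F / sqrt(2N)`,
normalized so identical matrices score 1 and fully mismatched hard
assignments score 0. `exact` enumerates all `K!` permutations (K ≤ 8);
`greedy` matches columns by smallest residual — the large-K strategy —
and is a lower bound that attains the optimum in ≥95% of replicate-run
pairs in the tests. The consensus subset is the run with the most
partners above SSC 0.90 plus those partners (ties to the lowest run
index); the mean Q-matrix averages the subset after aligning every run
onto the first member and renormalizes rows.

Breed assignment is majority-rule: an animal's primary cluster is its
argmax membership (ties to the lowest cluster index), a breed's home
cluster holds the plurality of its animals, clusters claimed by two or
more breeds are reported as shared (flagging the pairs for separate
re-analysis), and a breed whose best plurality is below two animals is
unassignable. The breed PCA operates on column-centered pooled allele
frequencies without variance scaling (a unit-variance flag exists); axis
significance permutes individuals among breeds, recomputes frequencies,
and compares axis eigenvalues.

## The simulator

Balding–Nichols-style Dirichlet drift: per locus, ancestral frequencies
are a flat Dirichlet draw over `m` alleles (m uniform in a configured
range, default 9–28); breed `i`'s frequencies are
`Dirichlet(ancestral * (1 - F_i)/F_i)`, so `F_i` controls both its
differentiation and its expected diversity loss (`E[He] ≈ (1 - F_i)
He_anc`). Admixture events replace a target's pre-drift base with a
convex mix of already-realized source-breed frequencies — introgression
acts on breed frequency vectors, keeping the truth analytic — and the
target then drifts around that base. Genotypes are drawn under
within-breed Hardy–Weinberg; null alleles are injected per allele copy
(visible/null appears homozygous, null/null appears missing); everything
is deterministic in the seed.

`study_config` fixes the emulated survey: 51 breeds sampled on a 12–55
grid, 21 loci, a skewed drift profile (most breeds mild, a few strongly
drifted) chosen so the global Weir–Cockerham θ lands near 0.12 while
breed He spans roughly 0.5–0.85, 2% missing data, and an
introgression-linked subset (five breeds 40%-introgressed by a hub, four
near-duplicates of it). `introgression_demo_config` is a compact
ten-breed version for the contribution-structure analyses: a
near-duplicate cluster, three partially introgressed isolates, and one
pure isolate that is both the most diverse and the most distinct.

What the simulator does *not* emulate: mutation models (stepwise or
otherwise), linkage, selection, pedigree structure, within-breed
substructure, and genotyping artefacts beyond nulls and uniform
missingness. Because drift alone couples divergence with diversity loss,
a breed can only be simultaneously high-He and highly distinct through
the admixture mechanism (as in the demo configuration); passing tests
therefore show the pipeline recovers truth under this generative model,
not that real surveys satisfy it. Under the flat-Dirichlet ancestor the
ancestral heterozygosity is high (≈0.85–0.88), so simulated He ranges sit
somewhat above typical field values at the same F.

## Numerical choices and problem sizes

Rarefaction uses log-gamma differences with the `C(2N - N_k, g)` term set
to zero when `N_k > 2N - g`. Dirichlet concentrations are clipped at
1e-9 to avoid underflow at extreme F. Tiny negative distances from
rounding (> −1e-12) are clamped to zero. Permutation p-values use
`(b + 1)/(m + 1)` throughout. Argmax-based rules (assignment, consensus
ties) resolve ties to the lowest index for determinism.

The test suite and the acceptance script run simulations at desk scale:
20 replicates of the 51 × 21 × 36 differentiation-recovery experiment,
500 equilibrium cells for test calibration at 199 permutations, 200
AMOVA-null replicates at 99 permutations, and 100 run pairs for the
alignment comparison — sizes chosen so the whole suite completes in well
under a minute while leaving the Monte-Carlo tolerances comfortably
wider than the observed spread.
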