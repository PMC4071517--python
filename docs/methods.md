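# Methods

This note documents the statistical model behind `kinscape`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Kinship from dominant markers

Dominant binary markers score only band presence/absence: the heterozygote
and the dominant homozygote are indistinguishable. Under Hardy–Weinberg
equilibrium the band-absence frequency equals q², so the presence-allele
frequency at a locus with band frequency f is p = 1 − √(1 − f). Each
phenotype is mapped to its expected per-gene-copy allele dosage,

- band absent → x = 0 (the genotype must be aa),
- band present → x = 1/(2 − p), since
  E[dosage | band] = (p² + pq)/(p² + 2pq) = 1/(2 − p).

A convenient identity follows: the sample mean of x at a locus equals p̂
exactly, because p̂(2 − p̂) = f̂.

Kinship between individuals i and j is a Loiselle-type moment estimator on
these dosage expectations:

    F_ij = Σ_l [ (x_il − p_l)(x_jl − p_l) + s²_l / (n_l − 1) ]
           / Σ_l p_l (1 − p_l)

with sums over loci non-missing in both individuals (pairwise-complete),
n_l the non-missing sample size at locus l, and s²_l the maximum-likelihood
variance of the dosage expectations about p_l. The correction term
s²_l/(n_l − 1) is the classical Loiselle small-sample correction applied to
the variable actually entering the estimator: for codominant per-copy
indicators s² = p(1 − p) and the classical form is recovered, while for
dominant dosage expectations s² = p/(2 − p) − p² < p(1 − p). Using the
dosage variance makes the estimator *exactly* centred: the off-diagonal
mean is identically zero for complete data (the binomial form would leave
a positive bias of order 1/((2 − p)(n − 1)), noticeable at n ≲ 100). The
binomial correction remains available via `correction="binomial"`.
Inbreeding is fixed at zero, consistent with assuming HWE; the diagonal is
left undefined and never used downstream.

## Predictor matrices

- **Geography** — haversine great-circle distance (Earth radius
  6,371,000 m) from decimal-degree coordinates. At within-island extents
  this differs from planar Euclidean distance by well under 0.1%; a planar
  option exists.
- **Environment, per variable** — |v_i − v_j| for each variable. Slope
  aspect is first converted to northeasterly wind exposure,
  180 − angular distance(aspect, 45°), so southwest-facing slopes score 0
  and northeast-facing slopes 180.
- **Environment, combined** — variables are centred, scaled to unit
  variance (sd with n − 1), rotated by PCA, and the Euclidean distance
  between score vectors is taken. All components are retained by default,
  in which case the rotation is an isometry and the matrix equals the
  Euclidean distance on the standardized table; a component cutoff is
  available but off by default.
- **Community** — each individual inherits the species set of its
  vegetation association; the predictor is the Jaccard dissimilarity
  1 − |S_i ∩ S_j|/|S_i ∪ S_j|, which is a metric.

All matrices are unfolded to the lower triangle (i > j, row-major; one
fixed pair order per run) and standardized to mean 0, sd 1. The response
(kinship vector) is standardized alongside, so effect sizes are
dimensionless and comparable across datasets. Collinearity is screened on
the unfolded vectors — the objects actually entering the regression — by
iteratively removing the predictor with the largest variance inflation
factor while any VIF = 1/(1 − R²) exceeds 5; ties drop the later predictor
in declared order. The screen is applied in the twelve-matrix design,
where near-duplicate environmental variables occur.

## All-subsets regression and model averaging

With p screened predictors, all 2^p submodels (including intercept-only)
are fitted by OLS. Each fit records its residual sum of squares, Gaussian
log-likelihood −m/2·(ln(2π·RSS/m) + 1), parameter count
k = slopes + intercept + residual variance, and

    AICc = −2 logLik + 2k + 2k(k+1)/(m − k − 1).

Akaike weights are w_g = exp(−Δ_g/2)/Σ_h exp(−Δ_h/2). Averaging is
*conditional* (natural): each term is averaged over the submodels that
contain it, with weights renormalized to that subset. Full-model
(shrinkage) averaging, which counts absent terms as zero, is available as
an option; it uniformly shrinks weakly supported effects. The
unconditional standard error uses the Burnham–Anderson
weighted-sum-of-roots form SE = Σ w′_g √(var_g + (θ̂_g − θ̄)²); the revised
√-of-weighted-sum variant is behind a flag. Confidence intervals use the
normal multiplier 1.96 — pair counts are in the hundreds to thousands, so
the t correction is far below reporting precision. Coefficient sampling
variances within a submodel use the conventional σ̂²(XᵀX)⁻¹ with
σ̂² = RSS/(m − slopes − 1). The intercept-only model is included in the
candidate set; it carries weight but no term estimates, so conditional
averages are unaffected beyond the weight renormalization.

Whether a CI excludes zero is a *nominal* criterion: the m = n(n−1)/2
pairwise observations are not independent, so final significance also
requires the permutation test below (dual criterion).

## Permutation inference and FDR

The null is built Mantel-style: the rows and columns of the kinship matrix
are permuted by one random relabelling of individuals per iteration, with
all predictor matrices fixed, and the entire all-subsets averaging
pipeline is re-run on each permuted response (B = 1000 by default). Since
relabelling only reorders the off-diagonal multiset, the standardized
response is permutation-invariant up to order and no re-standardization is
needed. For each term: z = (observed − null mean)/null sd, a normal-theory
p from z, and the empirical two-sided p = (1 + #{|null| ≥ |observed|})/(1 + B),
which cannot be zero. If the null sd degenerates to zero the z-score is
undefined and only the empirical p is reported.

Across the terms of a run, empirical p-values (the default; the
normal-theory p can be selected) are adjusted with Benjamini–Hochberg and
a term is a discovery at q ≤ 0.05. FDR is controlled within each run
(species); no cross-run pooling is done by default. With at most 12 tests,
density-estimated local-FDR methods are unstable, which is why step-up BH
is used. Note a discreteness constraint: the smallest possible q is
(#tests)/(B + 1), so the twelve-matrix design needs B ≥ 240 for any
discovery at 0.05 — one more reason the default is B = 1000.

Final classification: significant negative → *isolation* (relatedness
declines with that distance), significant positive → *counter-gradient*,
otherwise *none*. The implementation fits all submodels to the B permuted
responses in one vectorized pass over precomputed Gram-matrix inverses, so
a full 1000-permutation, three-predictor run takes well under a second.

## Synthetic-data generator

The generator emulates a small-island study design: n individuals placed
uniformly on a square landscape (default side 5 km), ten environmental
variables served as ASCII rasters (default 25 × 25 cells) with individuals
inheriting the value of their containing cell, a vegetation tessellation,
and L independent dominant loci. Per locus l and individual i,

    logit(p_il) = logit(p0_l) + u_l(x_i, y_i) + b_l e_i + c_l(assoc_i)
    y_il ~ Bernoulli(1 − (1 − p_il)²)

with p0_l ~ Uniform(0.1, 0.7), u_l a zero-mean squared-exponential
Gaussian random field (Cholesky-factorized on the sampled points), b_l ~
N(0, γ_E²) multiplying one standardized environmental variable, and c_l a
per-association effect. Key numerical and design choices:

- **Scale separation.** Genetic spatial autocorrelation has a long range
  (ρ_G = 1200 m) while environmental variation is a fine-grained
  microhabitat mosaic (ρ_env = 100 m, below the raster cell size) — the
  regime in which dispersal-driven and habitat-driven structure are
  empirically distinguishable, and the reason environmental studies use
  10 m-scale rasters. Long-range environmental fields would be partially
  confounded with any smooth spatial genetic surface, and a linear
  geographic-distance term cannot absorb all of a Gaussian field's
  structure; with a coarse environment the combined design then shows
  small but systematic cross-predictor partials.
- **Associations** tessellate one environmental variable (default
  soil water, deliberately *not* the default IBE carrier, altitude) into
  quantile classes. Each association's species set is a sliding window
  over a 30-species pool, so community overlap decays strictly with
  environmental separation — IBC is correlated with but not identical to
  IBE.
- **Matched IBC covariance.** The per-association effects c_l are drawn
  with cov(c_a, c_b) = γ_C² · JaccardSimilarity(a, b) (the Jaccard
  similarity kernel is positive semidefinite), so expected relatedness
  declines *linearly* in the community dissimilarity predictor. With iid
  association effects, expected kinship would be a within/between
  indicator that Jaccard distance captures only nonlinearly, and the
  residual would leak into correlated environmental predictors.
- **Counter-gradient construction.** A positive-semidefinite relatedness
  structure cannot make whole groups more related across than within
  (between-group covariance is bounded by within-group variances), so
  broad-scale counter-gradient signal is impossible and the pattern must
  be carried by sparse kin structure. The generator therefore installs
  gradient-straddling kin pairs: individuals in the outer quarters of the
  environmental range copy each locus from the individual at the mirrored
  rank with probability γ_E (clonal or sibling propagules dispersed across
  the gradient). The most environmentally distant pairs become the most
  related and the matching per-variable coefficient turns significantly
  positive.
- **Calibrated strong settings.** `STRONG_EFFECTS` (γ_G = 0.7,
  γ_E = 0.35, γ_C = 0.8 on the logit scale) are calibrated at the default
  n = 60, L = 250 so that a single active effect is detected as isolation
  in ≥ 80% of runs (empirically ≈ 100%) while the two inactive predictors
  stay at their nominal false-positive rate. Larger values increase
  second-order suppression partials (e.g. a genuinely non-zero positive
  community coefficient induced through the soil-water content shared
  between the combined environmental distance and the tessellation) above
  the detection threshold; these are real properties of the generative
  model, not inferential errors, and mirror the attenuation/cancellation
  behaviour of amalgamated environmental distances.
- Determinism: one integer seed drives separate, deterministic generator
  streams for landscape and genotypes; identical configs give
  byte-identical output files.

What the generator does **not** emulate: linkage between loci, genotyping
error and band-size homoplasy, mutation/drift dynamics through time,
selection at individual loci, non-uniform sampling designs, and
least-cost-path dispersal. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
generative model, not robustness to these real-data complications.

## Problem sizes used in verification

The statistical acceptance checks use: 200 fully null replicates at
n = 40, L = 200, B = 199 for type-I calibration; 50 seeds per effect at
n = 60, L = 250, B = 199 (three-matrix) for recovery and power; a 3-point
effect grid at 20 seeds for monotonicity; 50 seeds at B = 499
(twelve-matrix) for counter-gradient classification; and n = 60, L = 300
for kinship centring. The brute-force model-averaging oracle covers
p ∈ {2, 3, 4} predictors and m ∈ [50, 500] pairs at 10⁻¹⁰ relative
tolerance.

## Known limitations

- The exact estimator used by established dominant-marker kinship software
  is not published alongside its binaries; the estimator here follows the
  Loiselle moment form on HWE dosage expectations and is pluggable, but
  numeric parity with any specific external tool is not claimed.
- Nominal CIs and permutation inference both inherit the
  non-independence of pairwise data; the permutation test is exact only
  under full exchangeability (the global null). Off-target predictors
  correlated with a strong active effect can show modestly inflated
  rejection rates — intrinsic to Mantel-style designs.
- Replicate-based locus filtering counts mismatches summed over all
  replicate pairs (a per-pair threshold is exposed via `max_mismatches`).
- The per-locus environmental effect acts on one variable; multi-variable
  effect mixtures can be composed by post-processing, as done for the
  mode-comparison cancellation scenario in the tests.
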