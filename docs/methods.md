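# Methods

## The state space

The state space is spanned by the first three gradients of resting-state
functional connectivity: D1 separates primary from association cortex, D2
visual from somato-motor cortex, and D3 the default-mode from the
fronto-parietal network. A subject's activation map for one task condition
is placed in this space by Spearman rank correlation with each gradient;
the coordinate on an axis measures how much the map's spatial pattern
resembles that axis' contrast of neural systems. Rank correlation makes
the coordinate invariant to any monotone rescaling of the map (so
arbitrary scaling of z-maps is irrelevant) and bounded in [−1, 1].

Ties receive average ranks and the correlation is computed as Pearson on
the ranks, which is exact under ties (the classical Σd² shortcut is not).

## The mixed model

Per dimension, locations are modelled with fixed effects for condition (13
levels), the five NEO-FFI traits, all trait-by-condition interactions, and
age, gender and mean framewise displacement as nuisance covariates, plus
random intercepts for subject and family and an i.i.d. residual. Because
every subject belongs to exactly one family the two random factors are
nested and the marginal covariance is block-diagonal by family; the REML
fitter profiles out the residual variance and the fixed effects and
optimizes the two variance ratios, factorizing each distinct family block
pattern once per objective evaluation. Estimates agree with lme4 to ~1e-7
(one test fits the same data through Rscript).

Inference conventions (chosen to match the lmerTest/emmeans defaults
without depending on them):

- **Coding.** The condition factor is deviation (sum-to-zero) coded and all
  continuous predictors are mean-centered, so the Wald F-test on a
  coefficient block is a Type-III test. The data-generating model is
  silent about trait scaling; generators default to standardized traits
  (mean 0, sd 1), with raw NEO-FFI-like scales available via
  `trait_means`/`trait_sds`. Gender enters as a centered 0/1 indicator.
- **Degrees of freedom.** Satterthwaite approximation: for a contrast ℓ,
  df = 2·(ℓᵀCℓ)² / Var(ℓᵀĈℓ), with the variance obtained from the
  REML-criterion Hessian (numerical, central differences with steps of
  1e-4 relative to each variance component, floored at 1% of the residual
  variance so boundary components remain differentiable). Multi-df F-tests
  decompose the contrast covariance by eigenvalues and combine the per-
  contrast dfs through the standard expected-value matching formula.
  Denominator dfs land near the number of subjects for between-subject
  terms and near the number of observations for within-subject terms, the
  pattern expected for this design.
- **Simple slopes.** slope(trait, condition) = ∂location/∂trait at that
  condition, assembled as a linear combination of the trait main effect
  and interaction coefficients. The releveling identity (refitting with
  that condition as reference level reproduces the slope as the trait's
  main coefficient) holds to ~1e-12 and is tested to 1e-8 across all 65
  trait-condition cells.
- **Boundary fits.** A variance component estimated at zero is reported
  with a logged warning, not an error — expected under null simulations.
- **Multiplicity.** The family counts every unordered condition pair
  crossed with traits and dimensions: C(13,2)·5·3 = 1170, giving
  α = 0.05/1170 ≈ 4.27e-5 at the 5% family-wise level.

## Bootstrap sign stability

For a flagged interaction, the follow-up statistic is the bivariate
Pearson correlation (no covariates) between the trait and the per-subject
divergence score — the difference of the two most divergent conditions'
locations (largest vs. smallest slope t). Subjects are resampled with
replacement 1000 times at each of 16 log-spaced sizes from 25 to 950
(rounded exp-linspace, endpoints exact, duplicates dropped). Percentile
bands are equal-tailed (95%, 99%, and the full range). The stabilization
sample size at coverage c is the smallest ladder size from which onwards
the fraction of estimates sharing the full-sample estimate's sign is
strictly greater than c (the sustained rule prevents flicker; the
reference direction is the full-sample estimate's sign, logged with the
result). Iterations with undefined correlations (degenerate draws) are
redrawn and counted, keeping each distribution at exactly n_boot values.

The family-singleton variant uses 13 log-spaced sizes from 25 to 442 and,
in every iteration, first picks one representative member per family
uniformly at random and then draws families with replacement — so two
different members of one family can never co-occur within an iteration,
while ordinary bootstrap duplication of a subject remains possible.

The Fisher-z closed form n* = 3 + (z₀.₉₅ / atanh r)² predicts the 95%
stabilization size; the test suite verifies agreement within ladder
granularity at r = 0.2 (n* ≈ 69) and monotonicity in |r|.

## Synthetic cohort: what it emulates and what it does not

Generators are pure functions of their arguments and a seed.

- **Gradients** are sums of low-frequency sinusoids over a generic vertex
  index, orthogonalized and standardized: smooth, mutually decorrelated
  fields. They mimic the smoothness and orthogonality of real gradients
  but not cortical geometry, parcellation structure, or hemispheric
  symmetry.
- **Cohort** defaults: 950 subjects, of which ~53.5% form sibling pairs
  (leaving ≈442 singletons, matching the released sample's structure);
  ages uniform on 22–37 years; balanced 0/1 gender; standardized traits;
  per-task mean framewise displacement log-normal with median 0.15 mm and
  log-sd 0.35 (positive and right-skewed like real head motion).
- **Locations** follow the mixed model exactly
  (`generate_coordinates`), with default variance components
  sd_subject = 0.05, sd_family = 0.03, sd_noise = 0.08 in ρ units —
  chosen once so the between-subject spread of a condition's location is
  ~0.1, the scale seen in projected task maps. Covariate effects are
  applied to centered covariates so condition means stay interpretable.
- **Maps** (`generate_maps`) invert the projection: each map is
  Σ_d ρ_d·G_d + a·η with G the rank-standardized orthonormal basis, η a
  per-map noise field orthogonalized against the basis, and
  a = √(1 − |ρ|²), plus optional unstructured vertex noise (default sd
  0.1). Projections of generated maps correlate with their targets at
  r > 0.95 for ≥1000 vertices. Two known distortions: mild attenuation
  from the rank transform of the composite map, and a small constant
  leakage (~0.05) between dimensions because smooth fields are orthogonal
  but not statistically independent. Both are constant offsets/scalings
  across subjects, so slopes, interactions and stability results are
  unaffected; absolute condition centroids are approximate.

A green test on synthetic data therefore establishes the statistical
machinery (estimation, inference calibration, resampling), not any claim
about real cortical topography, task battery idiosyncrasies, trait
measurement error, or non-Gaussian trait-brain relationships.

## Numerical choices

- REML optimization: L-BFGS-B on the two variance ratios (bounds ≥ 0,
  ftol 1e-14) followed by a Nelder–Mead polish (xatol 1e-12); the
  criterion is invariant to the fixed-effect basis, which is what makes
  the releveling identity hold to high precision across refits.
- Rank-deficient fixed designs raise an error naming the collinear
  columns; unbalanced designs (subjects missing conditions) are handled
  by row omission.
- Satterthwaite dfs are clipped to [1, 1e7]; a non-positive gradient
  variance (possible at a variance boundary) yields the effectively
  infinite df cap rather than a spurious small df.
- Ties in the divergent-pair scan are broken by catalogue order with a
  logged warning.
- Pipeline determinism: one root seed is expanded via SeedSequence into
  per-stage streams; reruns are byte-identical for TSV/JSON payloads.

## Power conventions used in the tests

With the default variance scale, a planted slope of −0.02 ρ per trait sd
on one condition gives a noncentral-F interaction power of ~0.92 at
n = 400 subjects (the documented effect size/sample size for the power
test), and ~0.80 at n = 300. The type-I calibration test uses n = 300
under the null. The end-to-end tests plant ±0.05 on two conditions at
n = 500, where the flag is essentially certain at α = 4.27e-5.

## Known limitations

- No fMRI time series, preprocessing, surface geometry or CIFTI parsing:
  inputs are numeric vertex-grid matrices (an adapter can be layered on).
- Only random intercepts (no random slopes), REML only, Bonferroni only.
- The bootstrap is percentile-based; no BCa or studentized intervals.
- Satterthwaite relies on numerical differentiation of the REML
  criterion; with variance components exactly on the boundary the
  corresponding uncertainty is underestimated (dfs err toward large).
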