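# Methods

## Dynamic network construction

Windows are rectangular (no taper), 0-based and half-open: window m covers
[m·S, m·S + W), and trailing time points that do not fill a whole window are
dropped, so K = ⌊(T − W)/S⌋ + 1. Defaults follow common practice for
low-order (W = 60, S = 2) and high-order (W = 60, S = 10) networks; both are
plain constructor arguments. Correlations are raw Pearson values; a Fisher
z-transform is available (`fisher_z=True`) but off by default, since all
downstream statistics are computed per feature and an increasing transform
changes none of the selection decisions qualitatively.

A zero-variance ROI column inside a window makes the correlation undefined
and is treated as corrupt input: construction fails naming the window and
column. High-order construction is different — a constant connectivity
profile can arise legitimately (e.g., from a near-regular correlation
structure), so a degenerate profile correlation is recorded as 0 with a
logged warning instead of failing.

High-order profile vectors exclude **both** pair members: the profile of ROI
i against pair (i, j) is (ρᵢₘ)ₘ∉{i,j}, giving two index-aligned vectors of
length M − 2. The alternative reading — drop only each ROI's own diagonal
entry — is available as `profile="off_diagonal"`; exclude-both is the
default because it compares the two ROIs over an identical set of third
parties. This requires M ≥ 5 so the vectors have at least 3 entries.

## Moment features

Order 1 is the sequence mean; order d ≥ 2 is the population-normalized
central moment (1/K)Σ(x − x̄)ᵈ. The normalization constant is immaterial
downstream: the two-sample statistics and the z-scored SVM inputs are
invariant to it. A sign-preserving d-th-root scaling (sgn(m)|m|^(1/d)) is
provided for users who want all orders on the data scale; it is off by
default and untouched by the tests' planted-recovery claims. The seven-order
default covers location, scale, skew- and tail-type variation of an FC
sequence; the definition sits in one function (`central_moment_feature`) so
an alternative family can be swapped in.

Diagonals of all feature matrices are stored as 0 and excluded from every
vectorization; only i < j units exist downstream.

## Feature evaluation

- **t-test**: pooled-variance (Student) two-sample, two-sided. Degenerate
  inputs follow explicit conventions: both groups constant and equal → p = 1;
  both constant and different → p = 0.
- **chi-square**: continuous features are binarized at the pooled median
  (> median vs ≤) and a 2×2 group-by-bin chi-square statistic without
  continuity correction is evaluated; a constant feature (no split) gives
  p = 1. The tuned cutoff is interpreted as a p-value threshold — its
  standard grid reaches 1.0, which is meaningless for a statistic value.
- **Fisher score**: (n₁(μ₁−μ)² + n₂(μ₂−μ)²)/(n₁σ₁² + n₂σ₂²) with population
  variances; a zero denominator with separated means is capped at 1e12.

Each score carries an explicit orientation (p-values lower-better, Fisher
higher-better), and thresholding keeps p < cutoff or score ≥ cutoff. Default
tuning grids: p ∈ {0.01, …, 0.10}, chi-square ∈ {0.1, …, 1.0}, Fisher
∈ {0.01, 0.015, …, 0.05}. No multiple-testing correction is applied; the
cutoff is a tuned hyperparameter, not an inference level.

## Selection strategies

UPFFS scores each unit's D features across training subjects and keeps the
oriented best (ties to the lowest order); the winners form the fingerprint
matrix, and only units passing the threshold enter the final set — the same
tuned cutoff as the baselines, so the three strategies differ only in
*where* the threshold is applied. SVFS ranks whole orders by stratified
inner-CV accuracy of the downstream linear SVM (the one view-level criterion
that matches the classification objective), then thresholds inside the
winning view. CFS vectorizes in a fixed, documented order (order-major, then
row, then column of the upper triangle) so results are bit-reproducible.

Empty selections are hard errors at application time; the CV driver treats a
grid point whose selection is empty in any inner fold, or on the refit
training set, as invalid and skips it (logged). A fold where every grid
point is invalid fails loudly rather than silently degrading.

## Cross-validation protocol

Stratified outer folds (default 6) are repeated (default 10) with fresh
partitions; each outer-training set runs a stratified inner CV (default 5
folds) over the threshold × C grid (C ∈ 2⁻⁵…2⁵), maximizing pooled inner
accuracy, ties to the first grid point. Everything data-dependent —
evaluation scores, the SVFS view, standardization statistics (per-feature
z-scores), hyperparameters — is computed on training subjects only, and
`apply_selection` reads test-subject features without re-evaluation; a
poisoned-sentinel audit test asserts that garbage in the test fold changes
nothing about the fitted fold. Predictions are pooled across outer folds,
the six metrics computed once per repeat, and mean ± SD (sample SD over
repeats) reported. Undefined ratios (zero denominators) are reported as 0
and flagged.

For fusion, the low- and high-order arms share fold partitions so decision
scores align subject-by-subject. Each arm's (threshold, C) is tuned by inner
accuracy; α ∈ {0.1, …, 0.9} is then tuned on the winners' out-of-fold inner
decision scores. This sequential conditional search replaces a full
5-dimensional joint grid, which would cost ~100× more for a selection that
differs only by grid noise; the α stage still sees only training-fold
scores.

The SVM regularization parameter is C of a standard linear SVM — the only
free parameter a linear SVM has — searched over the canonical 2⁻⁵…2⁵ grid.

## Synthetic data

`generate_fc_dataset` emulates two-group collections of FC sequences in
which different units carry group differences in different moments. Each
subject × unit sequence is stationary AR(1) Gaussian (lag-1 autocorrelation
φ = 0.3 by default — consecutive overlapping windows share data, so FC
values are serially correlated) with subject-level random effects: sequence
mean ~ N(0.2, 0.1²) and multiplicative spread jitter exp(N(0, 0.1²)) on a
base within-sequence SD of 0.15, values typical of windowed correlation
traces. Effect sizes are expressed in pooled SDs of the feature's *null
subject-level distribution*, estimated once from a 4000-subject reference
sample drawn with a fixed internal seed, so planting never depends on the
generated cohort.

Plant mechanics per designated order d\*:

- d\* = 1: additive mean shift (exact, touches no other central moment);
- d\* = 2: within-sequence SD inflation. Because raw even moments co-move
  under scaling (m₄ ∝ c⁴), a tail-lightening sinh-arcsinh compensation is
  calibrated so the 4th-moment expectation returns toward its null value;
  without it the designated-moment semantics would be violated — a
  "variance" unit would carry an equally strong planted difference in m₄.
  The compensation is best-effort (bounded shape search).
- d\* ≥ 3: sinh-arcsinh shape transform of the innovations (skew parameter
  for odd orders, tail parameter for even), marginal re-standardized so mean
  and variance stay put, magnitude found by bisection against the target
  shift. Exactness is not claimed; calibration is verified to ±0.3 pooled
  SDs in tests. Odd (even) plants leak into higher odd (even) orders — e.g.,
  a skew plant also shifts m₅ — which is why planted-recovery claims are
  made for orders 1–2, the motivating mean/variance scenario.

Clipping sequences to [−1, 1] is available (and used in time-series demos)
but off by default, since it perturbs planted moments.

`generate_bold_dataset` instead plants signal at the ROI time-series level:
each group's scan concatenates Gaussian segments drawn from group-specific
covariance regimes (validated positive definite), so windowed correlations
differ exactly where the regime covariances do, exercising the window →
correlation → moment → selection chain end to end.

What the generator does *not* emulate: hemodynamics, scanner noise,
inter-regional dependence between units (units are drawn independently),
site effects, or realistic network topology. Passing tests therefore
demonstrate the pipeline's statistical machinery — recovery, ordering,
calibration, hygiene — not expected accuracy on real imaging cohorts.

## Problem sizes and test-time choices

The verification suite and `scripts/acceptance.py` run at desk scale, chosen
so the whole suite completes in minutes on one CPU: M = 8–12 ROIs, K = 40
windows, 18–30 subjects per group, 6 outer × 3 inner folds, 2–4 repeats,
threshold grid {0.01, 0.05, 0.1} (a subset of the standard grid) and
C ∈ {2⁻³, 2⁻¹, 2, 2³}. Strategy-ordering experiments use ten independently
seeded cohorts with four mean-, four variance- and four skew-discriminative
units at Δ = 1 pooled SD — heterogeneity across moments is exactly the
regime where a single view is structurally handicapped. The fingerprint
ordering versus the concatenation baseline is asserted on the mean over
cohorts; its per-cohort advantage (~1–3 accuracy points) is real but small
relative to per-cohort CV noise, so a seed-level sign test is reserved for
the single-view comparison, whose structural gap (~10 points) supports it.

## Known limitations

- The seven features are raw central moments; high orders (m₆, m₇) are
  heavy-tailed across subjects, which weakens t-test power there and makes
  even/odd orders compete with each other under shape plants.
- The chi-square evaluator's median binarization discards within-bin
  information; it is the deterministic, balance-preserving choice, not the
  most powerful one.
- Fusion tunes α after per-network hyperparameters (see above), so an
  interaction between a suboptimal per-network configuration and a better
  fused one is not searched.
- Decision scores of the two arms are fused unnormalized, as produced by
  each SVM; with standardized inputs their scales are comparable, but a
  pathological scale mismatch would bias the effective α.
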