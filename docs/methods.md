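# Methods

## The abnormality model

`normindex` measures how far a subject sits from the centroid of a reference
population in a space where the reference's dependency structure has been
removed. Given a reference matrix `Ref ∈ R^{n×p}` (n subjects, p features)
and a subject vector `s ∈ R^p`:

1. **Standardize.** Each feature is centered by the reference column mean
   `μ_j` and scaled by the reference column SD `σ_j` (n−1 denominator).
   Both the reference and the subject are standardized with the *reference's*
   parameters, so the reference centroid sits at the origin and each axis is
   in reference-SD units.
2. **Rotate.** The covariance of the standardized reference is its
   correlation matrix `R`. Its orthonormal eigenvectors `E` define the
   principal-component basis; `E^T z` re-expresses a standardized vector in
   uncorrelated coordinates. A rotation changes no distances — only the
   coordinate system.
3. **Whiten.** Component `j` is divided by `√λ_j`, the reference SD along
   that component, giving every retained component unit reference variance.
4. **Measure.** Any distance from the origin of the whitened score vector is
   an abnormality score; with all components retained the Euclidean version
   equals the Mahalanobis distance `√(z^T R^{-1} z)`.

The crucial property for high-dimensional use: when `p ≥ n`, `R` is singular
and the Mahalanobis distance is undefined, but a centered n-row matrix has at
most `n−1` non-zero eigenvalues and the whitened distance over those
components is still well defined. The pipeline therefore caps the retained
rank at `min(n−1, p)` and truncates components with
`λ < zero_tol·λ_1` (default `zero_tol = 1e−10`) *before* the `√λ` division,
so numerically-zero directions can never blow up a score.

Numerical route: the eigenpairs come from an SVD of `Z/√(n−1)` rather than an
explicit eigendecomposition of `Z^T Z`, which is better conditioned when
`p ≫ n` and never forms the p×p matrix. Eigenvalues are the squared singular
values; ties keep decomposition order (stable sort). Eigenvector signs are
fixed by making each component's largest-magnitude loading positive, so score
signs are reproducible across BLAS implementations (distances are
sign-invariant either way).

Useful identities that the tests exercise: the pre-truncation eigenvalues sum
to `p` (trace of a correlation matrix); each whitened reference score column
has sum of squares `n−1`, so the mean squared whitened distance over the
reference is `m(n−1)/n`; and full-PC whitened distances are invariant to any
fixed orthogonal rotation of the standardized data.

## Component retention

Whitening divides by `√λ`, so near-zero components amplify noise; retention
rules trade that against information loss. All of the standard criteria are
implemented in `normindex.selection`:

- **TVE**: smallest k whose cumulative eigenvalue sum reaches a cutoff
  (0.90/0.95/0.99 conventionally) of the *full* trace p. With a
  rank-truncated basis a high cutoff may be unattainable; then k = m with a
  warning.
- **Kaiser–Guttman**: keep eigenvalues strictly > 1 — a component carrying
  more variance than any single standardized feature. If nothing exceeds 1
  the decision is k = 0 with a degenerate flag (a caller asking to *measure*
  with k = 0 gets an error).
- **Broken stick**: keep the leading run of components whose variance
  proportion exceeds `b_k = (1/p)Σ_{i=k..p} 1/i`, the expected k-th longest
  piece of a unit stick broken at p−1 uniform points. Strict inequality; the
  run stops at the first failure (non-contiguous passes do not count —
  conventional, and it keeps retained sets contiguous).
- **Parallel analysis**: keep the leading run of components whose eigenvalue
  exceeds the per-component `quantile` (default 0.95) of eigenvalues from
  `n_reps` uncorrelated standard-normal datasets of the same n×p shape, each
  processed through the identical standardize-and-decompose path.
- **Bootstrap CI retention** for `p ≫ n`, where sample eigenvalues are not
  consistent estimators: rows are resampled with replacement, the whole
  standardize/decompose pipeline refit per replicate, and one-sided
  percentile bounds at `conf_level` drive the decision. In eigenvalue mode
  the first component whose upper bound falls below 1 is the cutoff and
  everything before it is retained (the CI analogue of Kaiser–Guttman: a
  component is dropped only once it is confidently below 1). In TVE mode
  k is the first component whose cumulative-TVE lower bound reaches the
  cutoff, and that component is included, since the test certifies the
  variance target has been met. Replicates that produce a constant column
  are redrawn and counted in the decision's warning field.

A caveat measured during development and asserted in the tests: percentile
CIs for *sorted* sample eigenvalues cover a well-separated population
eigenvalue at roughly nominal rate, but the extreme order statistics of a
*tied* population group are biased (the largest of a tied triple is pulled
up, the smallest down), so their coverage is structurally below nominal.
Retention decisions are unaffected (they act on the separated leading part of
the spectrum), but eigenvalue CIs near ties should be read with that in mind.

## Distance measures and baselines

Over a whitened score vector of length k: `euclidean` (ℓ2), its square,
`manhattan` (ℓ1), `rms = ℓ2/√k`, `mad = ℓ1/k`, and `ln_euclidean = ln ℓ2`
(error at exactly zero norm). MAD is the most clinically interpretable —
"on average this subject is x reference SDs from normal per component" — and
`rms`/`mad` use the *retained* count k, since they describe the components in
use. The μ=100/σ=10 clinical rescaling z-scores a subject's raw score
against the reference cohort's raw scores and maps it to `100 − 10·z`
(higher = more normal, matching the established clinical index; the sign is
configurable).

Three prior gait-index conventions are available as baselines via
`baseline_index`: squared Euclidean over all whitened components (a full-PC
normalcy index), ln-Euclidean in the *standard* standardized basis (no
decorrelation — it inherits the multicollinearity bias), and the RMS
difference from the reference mean in raw units. The squared-Euclidean
baseline is not divided by the component count (the original index's
convention; configurable by composing `distance_from_origin` directly).

## The dimension-bias experiment

`run_bias_simulation` draws a reference of `n_ref = 100` from a multivariate
normal with unit variances and constant correlation `rho = 0.75`
(eigenvalues `1+(p−1)ρ` once and `1−ρ` repeated), then scores two probes per
replicate: all-ones, and a random half +1 / half −1 vector. Standard-basis
measures rate them identically at every p; the whitened PC basis rates the
anti-aligned probe increasingly abnormal with p, since its z-vector lives in
the `1−ρ = 0.25` eigenspace (population distance `√(p/0.25) = 2√p`) while
the aligned probe lives along the large eigenvalue (population distance
`√(p/(1+ρ(p−1)))`, bounded by `√(1/ρ)`). One reference draw is shared by
both probes per replicate (pairing the comparison), the reference is
standardized by its own sample moments exactly as with real data, and each
replicate's generator is seeded `SeedSequence([seed, p, rep])`, so the grid
is embarrassingly parallel yet reproducible. Defaults match the experiment
this package demonstrates: p grid (2,4,…,50 in the conventional steps),
500 replicates; scaled-down runs (100 replicates, p ∈ {2,10,50}) are used in
the tests and acceptance script to stay fast on one CPU.

Finite-sample note: because the basis is *estimated* from n rows, the
expected squared whitened distance of a fixed vector carries an
`(n−1)/(n−p−2)` inflation relative to the population value (the mean of an
inverse-Wishart). At p=50, n=100 that is a factor ≈1.44 on the distance, so
simulated means sit well above the population oracles as p/n grows; at
p ≤ 10 the inflation is under 7%. The same effect means PC-basis distances
at ρ=0 exceed standard-basis ones slightly even though the rotation itself
is distance-preserving; and MAD, unlike the Euclidean norm, is not rotation
invariant at all (a rotated ±1 vector concentrates toward
`E|component| = √(2/π)·ℓ2/√p`), so the two bases agree at ρ=0 in the
*between-subject* sense (no bias between the probes), not value-for-value.

## Synthetic gait data

`normindex.gait` generates cohorts with the statistical structure of real
459-dimensional gait matrices without claiming biomechanical fidelity. Nine
named joint angles (pelvis ×3, hip ×3, knee flexion, ankle dorsiflexion,
foot progression) are sampled at 2% increments of the gait cycle (51 points)
and flattened angle-major. Each subject is

`curves = mean + Σ_f score_f · basis_f + smooth noise`,

with q = 12 smooth factors: half near-constant "offset" shapes (real
inter-subject variability is dominated by offset-like modes such as overall
pelvic tilt), half low-order sinusoids; each factor loads on all nine angles
with fixed positive-biased weights drawn once from a frozen model seed, so
within-angle correlations are predominantly positive and loading vectors
cluster by angle. Factor-score SDs decay geometrically from 4°, and the
residual is a per-angle mix of four random harmonics scaled to 0.6° SD —
smooth, like real kinematic noise after gait-cycle averaging. Consequences
the tests assert: a 32-subject cohort has ≤ 31 non-zero eigenvalues, 100%
TVE by component 32, trace 459 after standardization, and a Kaiser–Guttman
count well inside (3, 31).

What the generator does *not* emulate: stride-to-stride variability within a
session, measurement artifacts (marker placement, soft-tissue motion),
asymmetry between sides, and non-Gaussian subject populations. Passing tests
on this generator show the pipeline's algebra and its sensitivity behavior,
not clinical validity on real cohorts.

`generate_abnormal_subject` perturbs a reference draw with expected
abnormality monotone in `severity`: `amplitude` inflates the deviation from
the mean curves by `1 + 0.5·severity` (exaggerated but coordinated gait);
`offset` adds `severity·2°` per angle with alternating signs (static
malalignment); `phase` circularly time-shifts each angle by `severity·2`
cycle points with alternating signs — joints stay individually plausible but
lose their mutual timing. Phase is the designed "correlated" perturbation:
it mostly moves a subject along low-variance combinations of features, which
is why whitened PC measures separate severity groups that standard-basis
measures largely miss (the package's motivating phenomenon, reproduced
synthetically in the tests at two groups of 20, severities 1 vs 2, twelve
batches).

## Degenerate inputs and errors

Zero-variance reference features are a hard error naming the feature; missing
values are rejected at construction/load time (no imputation); subject files
with permuted or mismatched features are errors, never reordered silently;
`ln_euclidean` of an exact reference-mean subject is an error rather than
−∞; a retention decision of k = 0 cannot be used for measurement. Subjects
far outside reference support are still standardized by the reference σ —
no winsorizing is applied, by design: the index is supposed to report such
subjects as extremely abnormal.

## Problem sizes used in tests and the acceptance script

Worked example n=32, p=2 (closed-form oracle); gait cohorts 32×459;
Mahalanobis cross-check 50 instances of n=200, p=5 against a brute-force
inverse-correlation solve; bias experiment 100 replicates at p ∈ {2,10,50};
parallel/bootstrap checks at n ≤ 500, p ≤ 20 with 50–200 resamples; severity
study 12 batches of 2×20 subjects. These sizes keep the full suite around a
quarter minute while leaving every Monte-Carlo margin comfortably wide.
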