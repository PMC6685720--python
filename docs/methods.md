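# Methods

This note documents the statistical model behind `headimpact`, the meaning
and defaults of every parameter, what the synthetic-cohort generator does
and does not emulate, and the numerical choices made in the implementation.

## 1. Impact fingerprints

Each recorded impact carries a direction on the head: azimuth (degrees,
0° at the back of the head, +90° on the right, canonical range
[−180°, 180°)) and elevation (degrees, −90° inferior pole to +90° vertex).
Angles are canonicalized before binning: elevation outside [−90°, 90°] is
reflected about the pole (which flips the azimuth by 180°) and azimuth is
wrapped into the canonical range.

The **fingerprint** of a player is the histogram of their hits over a
10° × 10° azimuth–elevation grid — 36 azimuth × 18 elevation = **648
bins** — normalized to sum to one. Bins are half-open `[edge, edge + 10°)`
and flattened azimuth-major (`index = az_bin * 18 + el_bin`); the single
point at +90° elevation is closed into the top bin so that the binning is
total. A player with no hits gets an all-zero row, which downstream code
treats as "fingerprint undefined" rather than a valid distribution.
`FingerprintBinner` exposes the grid resolution as parameters
(`az_bin_deg`, `el_bin_deg`, defaults 10) and an optional `roster` so that
matrices are indexed by the cohort, not by whoever happens to appear in the
log.

## 2. Exposure summaries and thresholds

- Session summaries group hits into `practice` / `game` / `other` and
  report counts, percentages, and median/mean of both magnitudes.
- The cohort force threshold for a metric is **mean + 1 sample SD**
  (ddof = 1) of all hits in the log; it requires at least 2 hits.
- `count_suprathreshold` counts hits with magnitude ≥ threshold
  (threshold 0 therefore counts every hit); `count_exclusive` counts hits
  above one modality's threshold but below the other's.
- `decile_thresholds` returns the 10th–90th percentiles
  (`numpy.percentile`, linear interpolation) and requires ≥ 10 hits.

## 3. ROI extraction

FA volumes and masks are 3-D arrays plus a 4×4 voxel-to-world affine
(NIfTI convention, read and written with nibabel). Probabilistic atlas
volumes are binarized at a threshold (default 0.5, `≥`). Masks can only be
intersected on an identical grid (same shape, affines equal within 1e-4);
a mismatch is an error that names both shapes, never a silent resample.
`hemisphere_split` classifies voxels by world x-coordinate relative to a
mid-sagittal plane (default x = 0): strictly negative → left, strictly
positive → right; voxels on the plane are excluded and counted. Mean FA in
an empty mask is an error, not NaN. ΔFA is the signed difference
post − pre of mask means, with FA validated to [0, 1].

## 4. Group statistics

- **Paired pre/post tests**: two-sided paired t (closed form via the t
  distribution) and Wilcoxon signed-rank with zeros dropped; the Wilcoxon
  p is the exact null distribution (scipy `method="exact"`) for up to 25
  nonzero differences, else the normal approximation.
- **Spearman correlation** uses midranks for ties. For n ≤ 10 the
  two-sided p is an exact permutation p computed by enumerating all n!
  rank pairings (blocked at 500k permutations per chunk to bound memory);
  for larger n it uses the t approximation
  t = ρ·√((n−2)/(1−ρ²)) with n − 2 degrees of freedom. Constant input is
  flagged (NaN statistic), not silently zero.
- **Dose-response sweep**: for each threshold in a grid (default: the nine
  rotational deciles), correlate per-player suprathreshold counts with
  ΔFA in the chosen hemisphere (default right) by Spearman. Thresholds at
  which the counts or outcomes are constant are flagged `degenerate`.
- **Laterality index**: L = (ΔR − ΔL)/(|ΔR| + |ΔL|) ∈ [−1, 1], undefined
  (NaN) when both deltas are zero. It is antisymmetric under hemisphere
  exchange and invariant to positive rescaling of both deltas.
- **Tau association**: Spearman (default) or Pearson between plasma tau
  and postseason FA, dropping missing values, requiring n ≥ 4.

## 5. Leave-one-out ν-SVR and permutation inference

`LateralitySVR` predicts the laterality index from the 648-bin fingerprint
with a **linear ν-SVR** (scikit-learn `NuSVR` on a precomputed Gram
matrix). Under leave-one-out cross-validation each player is predicted by
a model trained on the other n − 1; the reported **out-of-fold r²** is the
squared Pearson correlation between held-out predictions and observations
(NaN if either side is constant, scored 0 in permutation nulls).

Numerical choices, all internal to the estimator:

- **Per-fold target standardization.** Targets are z-scored with training
  -fold statistics only; predictions are mapped back. A zero-variance
  training fold predicts the constant mean.
- **Gram normalization.** Fingerprint rows are probability vectors with
  ‖x‖² ≈ 0.02, so the raw linear kernel is tiny and the box-constrained
  dual cannot reach the spread of a z-scored target. Each fold's Gram
  matrix is rescaled to unit mean diagonal; the recovered primal weights
  fold the scale back in, so predictions are unchanged in meaning.
- **Defaults** `ν = 20/37` (the fraction of training rows kept as support
  vectors in a 38-player leave-one-out fold) and `C = 10`. With the kernel
  normalized and targets z-scored, C = 1 visibly underfits relative to a
  ridge-regression check on planted noiseless data, while C = 10 and
  C = 100 agree with it; C = 10 is the smaller of the two.
- **Relevance map.** For each bin, the squared correlation across folds
  between the fold's primal weight for that bin and the held-out
  laterality, with a two-sided t-approximate p-value and a Bonferroni mask
  at α/648 (0.05/648 ≈ 7.7e-5). Zero-variance weight trajectories get
  relevance 0.
- **Permutation test.** Labels are shuffled R times (default 1000) and the
  entire leave-one-out procedure is rerun per shuffle; the add-one p-value
  (1 + #{null ≥ observed})/(1 + R) can never be 0, so the smallest
  achievable p is 1/(R + 1). The Gram matrix is label-free, so per-fold
  kernel blocks are factored once and reused across all shuffles. For
  calibration studies that only need the reject/accept decision at a level
  α, an exact sequential shortcut stops as soon as the exceedance count
  guarantees p > α; because permutations are exchangeable this cannot
  change the decision.

The analytic critical value used for context is
r²*(α, df) = t²/(t² + df) with t the two-sided t quantile; at α = 0.01,
df = 37 this is ≈ 0.17.

## 6. Synthetic cohort generator

`simulate_cohort(CohortConfig)` produces a hit log, per-player outcomes,
fingerprints and a `ground_truth` record of everything planted. It is a
validation instrument: it emulates the *shape* of season-long exposure
well enough to exercise every estimator at realistic scale, and it makes
the true effects known exactly.

What it emulates, with defaults:

- **Exposure volume**: per-player hit counts are gamma-Poisson
  (mean 503 hits/season, gamma shape 2 → heavy right tail across players);
  sessions are practice/game/other with probabilities 0.59/0.37/0.04.
- **Magnitudes**: lognormal; linear log-mean ln 25 g, log-SD 0.68;
  rotational log-mean ln 1600 rad/s², log-SD 0.59; game sessions get a
  small positive log-shift (+0.01 linear, +0.03 rotational). This yields
  right-skewed distributions with game medians near 25 g and
  1600 rad/s² and a cohort mean + 1 SD rotational threshold around
  3000 rad/s².
- **Directions**: a mixture of von Mises clusters at the front and back of
  the head (concentration 4) plus a lateral component (fraction 0.2 at
  ±90°), with per-player front/back balance (Beta), per-player side
  preference (Beta) and per-player angular jitter (SD 10° azimuth, 5°
  elevation). The per-player heterogeneity is what makes fingerprints
  informative about the player rather than pure multinomial noise.
- **Planted dose-response**: ΔFA in the right hemisphere is
  β × (suprathreshold rotational count) + Gaussian noise
  (β default −5e-4 FA units per hit, noise SD 0.005 FA units), around a
  baseline FA ~ N(0.55, 0.02).
- **Planted directional map**: the laterality target is fingerprint ·
  weights + noise (SD 0.05), clipped to ±0.95; ΔFA in the left hemisphere
  is then back-solved so the realized laterality index equals the target
  exactly. `lateral_asymmetry_weights` builds a physiologically shaped
  right-positive/left-negative weight map (sin of azimuth, damped away
  from the equator) for recovery experiments; the default weight vector is
  all zeros (no planted map).
- **Tau subgroup**: the first 13 players get
  tau = 5.0 − 60 × (postseason right FA − 0.55) + noise (SD 0.5),
  a planted negative tau–FA association.

What it does **not** emulate: biomechanical coupling between impact
direction and strain, within-season temporal structure, scanner and
registration noise in FA, position-specific exposure profiles, or any
correlation between magnitude and direction. Conclusions about the real
world should come from real data; the generator exists so that estimator
behavior (bias, calibration, power) can be measured against known truth.

## 7. Validation strategy

- **Oracles**: binning, counts, mask algebra, mean-in-mask and tied
  Spearman are tested against independent brute-force reimplementations on
  thousands of random instances; Wilcoxon against exhaustive 2ⁿ sign
  enumeration; exact Spearman p against full n! enumeration.
- **Parameter recovery**: with the default planted negative dose-response,
  the decile sweep is negative at all nine thresholds in ≥ 90% of
  replicate cohorts.
- **Calibration**: under a planted null map, the SVR permutation test
  rejects at α = 0.05 at the nominal rate (within the binomial band over
  100 replicates).
- **Detection**: with a noiseless planted map and high per-player exposure
  the out-of-fold r² exceeds 0.9 and the permutation p is the smallest
  achievable.

## 8. Limitations

- The relevance-map p-values use a t approximation and treat folds as
  independent, which leave-one-out folds are not; the Bonferroni mask is
  conservative in the number of bins but the per-bin p is approximate.
- Out-of-fold r² as squared correlation is scale-free: it rewards
  monotone association, not calibration of predicted magnitudes.
- The laterality back-solve in the generator makes the planted map exact
  by construction; it does not model measurement error that is correlated
  between hemispheres.
- Hemisphere splitting assumes the volume is aligned so that the
  mid-sagittal plane is a world-x level set; oblique acquisitions must be
  resampled upstream.
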