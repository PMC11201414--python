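# Methods

This note documents the models implemented in `sonoliver`, the choices made
where the underlying procedures are under-determined, and what the synthetic
test bed does and does not establish.

## Image model and preprocessing

Images are 2-D float arrays in [0, 1], written as 8-bit grayscale.  The
degradation model is `g = h + m` with `m` a zero-mean Gaussian field of
standard deviation `noise_sigma`; output is clipped to [0, 1].  Although
ultrasound speckle is conventionally multiplicative, the additive form is
the package default because it is the form the rest of the pipeline is
specified against; `SpeckleMode.MULTIPLICATIVE` gives `h·(1+m)` for users
who want the conventional model.

Restoration is the classic local-statistics adaptive Wiener filter: with
local mean μ and variance σ² over a square window (3×3 default, odd sizes
configurable) and noise variance ν,

    out = μ + max(σ² − ν, 0) / max(σ², ν) · (in − μ).

ν defaults to the mean of the local variances — the standard estimator when
the noise level is unknown — and can be overridden.  Boundaries use
symmetric padding so that border statistics are not biased toward zero.
The filter passes edges (high σ²) nearly unchanged and averages flat
regions, and is exactly idempotent on constant images.  MSE/PSNR are
computed on the 0–255 intensity scale (PSNR = 10·log₁₀(255²/MSE), +∞ for
identical images).

## Synthetic two-class generator

Real cirrhosis image archives cannot be shipped, so the pipeline's test bed
is generated: each image is a correlated Gaussian field (white noise
smoothed at `correlation_length` px, rescaled to `base_variance`, centred
on `base_mean`), plus, for the cirrhotic class, bright Gaussian blobs
mimicking focal lesions.  Defaults: normal = mean 0.35, variance 0.010,
correlation length 6 px, no blobs; cirrhotic = mean 0.55, variance 0.020,
correlation length 3 px, 12 blobs of contrast 0.25.  These were chosen once
to emulate the qualitative contrast between classes — cirrhotic tissue
brighter, coarser, with focal structure — at a separation a texture
feature should resolve.

The generator does **not** model beam physics, attenuation, shadowing,
anatomy, or the heavy-tailed Rayleigh/Rician statistics of true speckle.
Passing tests on this data demonstrates that the pipeline's machinery is
correct and that its features separate textures that differ in first- and
second-order statistics; it does not certify clinical performance.  The
default classes are deliberately well separated, so pooled accuracies near
100% on synthetic data are expected and say nothing about the much harder
real-image problem.

## Clustering features

All three clustering algorithms operate on a seeded random subsample of at
most 4096 pixel intensities per image (clustering all ~10⁵ pixels adds cost
but no information at c = 3 clusters), with c = 3 by default (low / mid /
high echogenicity) and fuzzifier 2.

* **FCM** minimises Σ u^m d² subject to memberships summing to one per
  point, by the standard alternating updates (membership ∝ d^(−2/(m−1))
  normalised; centers = u^m-weighted means).  Initial centers are drawn
  from *distinct* data values so duplicated intensities cannot collapse two
  centers at initialisation.
* **PCM** is seeded from an FCM fit (it is initialisation-sensitive and
  prone to coincident clusters from cold starts).  The per-cluster scales
  η_a = β·Σu^m d²/Σu^m are computed once from the initialisation (β = 1
  default; a flag forces η_a = 1, the other published reading).  Typicality
  update: v = 1/(1 + (d²/η)^(1/(m−1))); centers are v^m-weighted means.
  The recorded objective is Σ v^m d² + Σ_a η_a Σ_b (1−v)^m — the canonical
  possibilistic objective whose coordinate minimisers these updates are,
  which guarantees the non-increasing trace that the tests assert.  (A
  variant that omits the η_a weight on the second term appears in print but
  is not the function the updates minimise; recording it would break
  monotonicity.)
* **PFCM** combines both: the objective weights memberships and
  typicalities by `a_weight` (C_FCM) and `b_weight` (C_PCM), with
  per-cluster scales γ estimated as in PCM.  The typicality update keeps
  the C_PCM factor inside the root (the exact minimiser), so (a=1, b=0)
  reduces exactly to FCM and (a=0, b=1) to PCM — both reductions are
  tested to 1e-6.

**Sample entropy** uses the Richman–Moorman convention: both template
lengths m and m+1 are counted over the same N−m starting offsets, matches
are Chebyshev-within r·std (r = 0.2, m = 2 defaults; the community
convention), self-matches excluded, result −ln(A/B).  A constant series
returns 0; A = 0 returns +∞ (capped at 10 when embedded in a feature
vector).  The image-to-series mapping is a row-major flatten of the central
32×32 patch (per-row means available as an alternative).

Feature vectors are: sorted cluster centers, then per-cluster mean
membership and (when defined) mean typicality ordered by the sorted
centers — a fixed-length, order-canonical summary of exactly what the
fitted model exposes; or, for sample entropy, [SampEn(m=1), SampEn(m=2),
series mean, series std].  Min–max normalisation to [0, 1] is fitted on
training folds only and clips held-out values, so no test-fold statistics
ever leak into training.

## Statistical characterisation

`summarize_features` reports per-(method, class): pooled mean, unbiased
variance, standardized skewness, *excess* kurtosis (the published values it
mirrors include negatives, which forces the Gaussian-relative reading),
an intra-class Pearson correlation (between the two halves of the class's
feature columns — the published pairing is not recoverable, so this fixed
convention is documented rather than matched), and the first canonical
correlation between the two class blocks, computed by SVD of the whitened
cross-covariance with a 1e-8 ridge under rank deficiency.  CCA is invariant
(tested to 1e-9) under separate invertible affine transforms of each block.

## Target coding and classifiers

Binary labels are coded normal → 0, abnormal → 1 internally and mapped to
continuous targets 0.1 / 0.85 for regression-style decisions; the scheme
enforces a separation of at least 0.5.  A diagnostic check warns (never
errors) when class-mean normalized features exceed their target bound —
with the default features the normal-class mean sits well above 0.1, and
the warning documents that the bound is aspirational for this feature set.
All argmax ties break toward the normal class and are logged.

* **GMM**: one full-covariance mixture per class (equal priors), fitted by
  EM with a covariance ridge of 1e-6·tr(Σ)/d; means seeded from data
  points; the per-iteration mean log-likelihood is recorded (non-decreasing
  by construction) and components whose weight collapses below 1e-8 are
  pruned with a warning after convergence.  Prediction is argmax class
  log-density.  sklearn's mixture implementation is used in the test suite
  as an independent cross-check, never in the implementation.
* **SDC**: stores the training vectors; class score is the stabilised
  log-sum-exp of −λ‖x − xᵢ‖² with λ = 0.5.  As λ → 0 scores tend to
  log(class size); a stored vector always wins for itself when the other
  class is distant.
* **SVM**: soft-margin dual SVM (SMO-style solver) with kernels
  x·y, (γ x·y + 1)^degree, exp(−γ‖x−y‖²).  Configured defaults:
  linear C = 0.85, class weight 0.4; polynomial C = 0.8, γ = 10,
  degree 2, class weight 0.5; RBF C = 0.8, γ = 100, class weight 0.87 —
  the class weight multiplies C for the abnormal class.  Labels ±1; KKT
  tolerance 1e-4.  Note γ = 100 on [0,1]-normalized features makes the RBF
  kernel nearly diagonal, so this classifier behaves like a narrow Parzen
  window; it stays above chance but below its better-tuned siblings on the
  synthetic benchmark, and that is faithful to the configured parameters.
* **Harmony search** (per-image, training-free): the search fits a harmony
  vector to the image's normalized feature vector under MSE over the box
  [0.1, 1]^d (the normalized feature range); the image takes the class
  whose target is nearer the best harmony's mean.  Memory size 16, HMCR
  0.9, initial PAR 0.3, stop at MSE ≤ 1e-5 or 1000 improvisations.  The
  improvisation step uses the improved-HS schedule: bandwidth decays
  exponentially from 0.1 to 0.005 over the run while the pitch-adjust rate
  ramps to 0.99, and pitch adjustment perturbs around the best harmony's
  value (the global-best variant).  These scheduling choices are what let
  the search hit 1e-3 on the 2-D sphere within 500 evaluations in
  essentially every seeded run.
* **AAO** (artificial algae): colonies move helically in three random
  coordinate planes toward tournament-selected sources with step
  (shear − τ(H))·{p, cos α, sin β}, where τ(H) = 2π(3H/4π)^(2/3) is the
  hemisphere-surface friction of a colony of size H (capped at 0.98·shear).
  Energy is the fitness rank raised to 2.5 (concentrating evaluations on
  good colonies); a colony moves while it can afford a full move, a failed
  move costing `energy_loss` (0.4) and a successful one half that.  Colony
  size grows by the Monod rate e/(L+e) (L = 0.5) on every successful move
  and shrinks slightly (÷1.05) on every failure, so the friction term acts
  as a success-driven step-size adaptation: consistently improving colonies
  take ever finer steps while stalled ones regain reach.  Non-improving
  colonies starve (their starvation drifts up stochastically toward and
  past the population maximum), and with probability `adaptation_rate`
  (0.3) the most-starved colony is pulled toward the biggest and its
  starvation reset.  Shear 3, loss 0.4, adaptation 0.3 are the configured
  operating point and also the sphere-benchmark setting.
* **AAO–GMM hybrid**: the algae search explores a vector encoding the
  mixture component count (1–3) and per-component EM starting means
  (offsets in units of the class spread); each candidate is scored by
  internal ten-fold output MSE of its predictions against the encoded
  targets (EM capped at 25 iterations during the search), and the winner is
  refit by full EM.  The plain seeded-EM configuration for each component
  count is evaluated as a baseline and retained if the search finds nothing
  better, so the hybrid is never constructed worse than its base model on
  the search criterion.  Default budget: 6 colonies, 40 evaluations.

The per-image optimizer classifiers effectively threshold the mean of the
normalized feature vector at (0.1+0.85)/2; they are training-free by
construction, which is the reading most consistent with a per-image
best-vector procedure plus fixed class targets.

## Evaluation layer

From (TP, TN, FP, FN): accuracy and error rate in percent with
ER = 100 − accuracy exactly (the printed alternative, (FN+TP)/total,
contradicts every published value it accompanies and is treated as a typo);
F1 and Jaccard in percent; MCC as a fraction in [−1, 1] with a 0 sentinel
when a denominator factor vanishes; F-measure as √(precision·recall) (the
geometric mean matches the published values; the arithmetic product does
not).  Reported values are rounded half-away-from-zero to 2 decimals;
internally full precision is kept.  Identities accuracy + ER = 100 and
JM = F1/(2 − F1/100) hold algebraically and are property-tested.

Cross-validation is stratified ten-fold (fold assignment seeded); the
normaliser and model are fitted inside each training fold; per-fold
confusions are pooled by summation (micro-averaging) and per-fold metric
reports are retained.  Output MSE is the mean squared deviation of the
continuous outputs from the encoded targets.

`reproduce_tables` recomputes all metrics from a table of labelled
confusion matrices and flags rows whose supplied expected values differ
from the recomputation by more than 0.01.  Applied to the shipped
published-benchmark table: most F1/MCC/F-measure/JM cells reproduce to 2
decimals (±0.01 rounding drift on some), while the benchmark's headline
accuracy cells are consistent with a different (smaller) test set than the
confusion matrices and are flagged rather than matched — most notably the
99.03% headline row, whose own confusion matrix yields 95.27%.

## Problem sizes and numerical choices

The synthetic benchmark used by the acceptance checks runs 40 images per
class at 96×96 px over 5 seeds with ten-fold CV for all eight classifiers —
sizes chosen to exercise every code path at comfortable cost.  Clustering
tolerance 1e-6 on the objective, max 200 iterations; EM tolerance 1e-6 on
mean log-likelihood, max 100 iterations; SVM KKT tolerance 1e-4.  All
randomness flows from one root seed through named SHA-256 substreams
(images, speckle, clustering, folds, optimizers), so identical configs
reproduce identical outputs byte-for-byte and stages can be rerun
independently.

## Known limitations

* The synthetic classes are far easier than clinical data; reported
  synthetic accuracies are a mechanism check, not a clinical claim.
* PCM's coincident-cluster pathology is mitigated, not removed, by FCM
  seeding.
* The per-image optimizer classifiers ignore training data entirely; their
  accuracy is a property of the feature normalisation and target placement.
* Binary classification only; no probability calibration; no ROC analysis
  (the evaluation layer is confusion-matrix based).
* The feature-statistics pairing conventions (intra-class PCC, class-block
  CCA) are fixed documented choices among several defensible ones.
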