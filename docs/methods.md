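# Methods

## Problem and pipeline

The package implements a segment-level PPG classification study: per-subject
single-channel photoplethysmograms sampled at 200 samples/s are cut into
one-second segments (200 samples each; 720 per full-length subject), each
segment is reduced from 200 samples to 100 features by one of five methods,
and twelve classifiers assign each reduced segment to CVD or normal.
Performance is reported per (reduction, classifier) cell as the fold average
of a six-metric confusion-matrix suite under stratified 10-fold
cross-validation with CVD as the positive class.  Beat-to-beat analysis is
deliberately out of scope: the segment, not the beat, is the unit throughout.

## Synthetic cohorts

The original clinical recordings are not redistributable, so the
`synth` module generates seeded surrogate cohorts with the same shape:
by default 20 CVD + 21 normal subjects, 144,000 samples each (720 s at
200 samples/s).

Each beat is the sum of two Gaussian lobes on the beat-phase axis — a
systolic peak (amplitude 1.0, center 0.30 of the beat interval, width 0.085)
and a dicrotic wave (amplitude 0.45, center 0.62, width 0.12) — riding on a
perfusion baseline of 0.5 signal units.  Beat intervals are Gamma-distributed
(positive, right-skewed) with class heart-rate means of 76 (CVD) and 68
(normal) beats/min and a healthy coefficient of variation of 0.05.  White
noise (sd 0.05) and sparse motion-artifact bumps (0.5/min, amplitude 1.5–3,
width 0.15–0.5 s) are added on top.

Disease scales four effects with the single knob `morphology_shift ∈ [0,1]`,
all vanishing at shift 0:

| effect | factor at shift *s* |
|---|---|
| whole-pulse amplitude | × (1 − 0.6 s) |
| dicrotic amplitude (additional) | × (1 − 0.6 s) |
| systolic width | × (1 + 0.4 s) |
| perfusion baseline | × (1 − 0.5 s) |
| interval CV | × (1 + 0.5 s) |

The amplitude and baseline damping are the standard reduced-peripheral-
perfusion signatures.  They are essential here: because one-second windows
slice the beat train at arbitrary phase, purely morphological effects
(dicrotic shape, systolic width) average out of the segment-level class
means, and without an amplitude/DC component no segment-level classifier —
not even a nearest-centroid oracle — can separate the classes.  With them,
a shift of 0.9 yields a cohort where nearest-centroid accuracy on envelope
features is ≈ 0.99 and every classifier-method cell clears 90%.

What the generator does **not** emulate: respiratory modulation, baseline
wander, sensor-specific transfer functions, inter-subject template
variability, or any physiologically validated hemodynamics.  Passing tests
on this cohort demonstrate that the pipeline's machinery behaves correctly
on separable quasi-periodic data; they say nothing about clinical accuracy
on real recordings.

`generate_feature_blobs` provides the classifier-test fixture: two Gaussian
clouds with identity covariance whose means are a prescribed Euclidean
distance apart.  The offset direction is a fixed sinusoid across the feature
index (unit norm, `max(1, dim // 16)` cycles) rather than a random vector:
distance-based classifiers only see the separation, while classifiers
sensitive to the within-vector shape (the DFA profile, piecewise
detrending) receive a structured, reproducible difference.

## Segmentation and denoising

`segment` cuts each record into `floor(len/fs)` contiguous non-overlapping
one-second rows; a trailing remainder shorter than one segment is dropped
and logged (never padded), so a 144,000-sample subject yields exactly 720
segments and a 41-subject cohort 29,520.

`denoise` offers an artifact-removal heuristic for single-channel data,
off by default: the segment matrix is treated as multivariate data with
segments as variables and time samples as observations, whitened by SVD, and
the component with the highest sample kurtosis — the usual heavy-tailed
artifact proxy — is removed before back-projection.  True independent-
component separation is ill-posed for one channel; this construction keeps
the named preprocessing step available without making the main pipeline
depend on it.  A rank-deficient matrix falls back to the identity with a
warning.

## Dimensionality reduction

All five methods map a 200-sample segment to exactly 100 features.

**Hilbert envelope (`HT`).**  The analytic signal `x + iH(x)` is built by
the frequency-domain method (zeroing negative frequencies); its magnitude is
the envelope, and the even-indexed envelope samples are kept.  The envelope
never falls below `|x|` pointwise, and `H` preserves the magnitude spectrum
at all non-DC, non-Nyquist bins.

**Nonlinear regression (`NLR`).**  Each segment is fit with a sum of
`n_kernels = 4` Gaussian lobes (12 free parameters) by Levenberg–Marquardt
least squares with three jittered starts (best residual kept, analytic
Jacobian); features are the fitted curve at 100 equispaced points.  Four
lobes give the two-lobe pulse morphology headroom for two partial beats per
window.  Widths enter through their absolute value so the optimizer is
unconstrained.

**Metaheuristic selection (`ABC_PSO`, `CUCKOO`, `DRAGONFLY`).**  The three
swarm methods share one construction: a candidate is a real vector over the
200 sample positions, binarized by `sigmoid(position) > 0.5` and repaired to
exactly 100 selected columns by flipping the lowest-impact bits under a
per-column class-separation ranking (standardized class-mean difference;
plain variance when only one class is present).  Fitness is
`F = a·φ(K) + b·(T−K)/T` with `a = 0.8`, `b = 0.2`: `φ(K)` is the accuracy
of a nearest-centroid probe on a fixed, seeded 70/30 stratified hold-out
split, restricted to the masked columns, computed on a seeded subsample of
at most 2000 segments for tractability.  Initial positions use a
per-individual density bias spread over [−2, 2], so the starting population
ranges from near-empty to near-full masks; the count repair then seeds it
with both random and ranking-guided candidates.  All three selectors are
elitist (the best mask's fitness never decreases) and fully deterministic
given the seed.

* ABC-PSO: employed and onlooker bees mutate single dimensions of personal
  bests with greedy acceptance (onlookers chosen fitness-proportionally);
  the scout phase is replaced by a PSO velocity/position update toward the
  personal and global bests (acceleration coefficients 1.5/1.5, velocity
  clipped to ±4, positions to ±6).
* Cuckoo search: per generation each nest proposes
  `z' = z + β ⊛ Levy(γ)` (entry-wise, step scale β = 0.5) and replaces a
  random nest if fitter; the worst 25% of nests (never the best) are rebuilt
  uniformly.  Lévy steps come from Mantegna's algorithm with stability
  parameter γ − 1, giving a step-density tail exponent γ (default 2.5).
* Dragonfly: step vectors combine separation, alignment, cohesion (weights
  0.1/0.1/0.7), attraction to the best position (1.0), the enemy term (1.0)
  and inertia (0.9).  The enemy term is implemented in its printed additive
  form `Q⁻ + Q`; `enemy_conventional=True` switches to the conventional
  repulsion `Q⁻ − Q`.

## Descriptor panel

`stats_features` computes, per method and class: mean, sample variance
(n−1), Fisher skewness, excess kurtosis (normal → 0; flat data negative,
peaked positive); the mean Pearson correlation over distinct within-class
segment pairs (seeded subsample above 10⁴ pairs; zero-variance segments
excluded with a warning); sample entropy SampEn(m=2, r=0.2·sd) with the
Richman–Moorman counting convention (identical template counts at both
lengths, Chebyshev distance, self-matches excluded — a constant or strictly
alternating series scores exactly 0, and zero matches give +inf, flagged);
and the first canonical correlation between the two classes' feature
matrices (columns as variables, rows paired in order and truncated to the
shorter class, ridge-regularized covariances, clipped to [0, 1]).
`sample_entropy(m, r)` is non-increasing in r; all descriptors are invariant
to segment order.

## Classifiers

All twelve kinds share the contract: fit on training features with coded
targets, emit one score per test segment, threshold it.  The emitted labels
are the thresholded scores by construction.  Targets default to 0.85 (CVD)
and 0.1 (normal); codings with a gap under 0.5 are rejected.  Iterative
kinds stop at training MSE ≤ 1e-5 or 1000 iterations, whichever first.
Score-producing kinds whose natural threshold is not stated use the coding
midpoint 0.475; logistic regression uses 0.5 and PCA 0.72.

Notable constructions and defaults:

* **PCA** projects onto the first principal axis of the training data,
  oriented so the CVD mean is high.  The projection is normalized by
  mapping the training class means onto the coded targets (0.1/0.85) and
  clipping to [0, 1] — the same normalization convention the target-coded
  kinds use — rather than by the raw min/max, which would park the CVD
  cluster too close to the 0.72 threshold.
* **EM** fits a 2-component Gaussian mixture to the pooled training
  features (diagonal covariances by default, `covariance_type="full"`
  available); components map to classes by responsibility-weighted label
  majority, and the score is the CVD component's posterior.  The mean
  log-likelihood is recorded per iteration and asserted non-decreasing on
  every fit; a decrease raises.
* **GMM** fits one mixture per class (2 components each) and scores with
  the dimension-normalized log-likelihood ratio squashed through a sigmoid.
* **BLDC** uses class means with a pooled covariance (ridge-regularized
  with a warning when singular), equal priors, decision threshold D = 0.
* **FIREFLY / HARMONY** optimize a pair of class prototypes against the
  coded-target MSE of nearest-prototype scores and classify by proximity,
  with the score mapped so it crosses the coding midpoint exactly at equal
  distances.  Populations are initialized around the training class means
  (the firefly population with seeded jitter; the harmony memory with one
  class-mean member plus uniform-random harmonies in the feature box),
  since a random box start cannot reliably find a two-prototype solution.
  Firefly: brightness 1/MSE, attractiveness `0.65·exp(−βr²)` with the
  absorption β defaulting to 1/(2d) so attraction is non-negligible at
  typical prototype distances, randomization 0.1.  Harmony: memory 12,
  memory-consideration rate 0.9, pitch-adjustment rate 0.3, bandwidth 0.004
  of the per-dimension span.  Both record the best-MSE trace, which is
  non-increasing by construction.
* **DFA** computes, per feature vector, the detrended-fluctuation function:
  cumulative mean-removed profile, per-window least-squares line fits over
  the window grid {4, 8, 16, 32}, RMS residual F(n).  Classification uses
  the full log F(n) profile with a nearest standardized-class-mean rule.
  The scaling exponent (the log–log slope, ≈0.5 for white noise, ≈1.5 for
  Brownian paths) is exposed by `dfa_exponent` and reported per class, but
  the profile is what discriminates: the slope alone is blind to class
  differences that sit in fluctuation magnitude rather than scaling shape.
* **PAC_BAYES** places a Gibbs posterior over single-feature threshold
  stumps (9 deciles × both polarities per feature) with weights
  `exp(−c·√n·err)`, c = 2, under a uniform prior; the score is the
  posterior-weighted mean of coded stump votes.  The √n rate keeps the
  posterior an ensemble over all competitive stumps — an n-linear rate
  collapses it onto the single best stump, which is strictly weaker than
  the vote.
* **KNN_PAC** appends the PAC-Bayes score as an extra column to the
  standardized features and runs k-NN with k chosen from {3, 5, 7} on a
  seeded 80/20 hold-out.
* **SDC** scores each class as `log Σ_i exp(−λ‖x − x_i‖²)` over that
  class's training samples, λ = 0.5, computed with log-sum-exp in chunks;
  **DETREND_SDC** first subtracts per-window least-squares lines (window
  length d/4) from every feature vector.

Feature standardization (training mean/sd, unit floor on sd) is applied
inside the kinds that are scale-sensitive; DFA works on raw vectors and the
PAC-Bayes stumps are quantile-based, hence scale-free.

## Evaluation protocol

`run_grid` reduces the cohort once per method (swarm masks are fit on the
pooled, segment-labeled cohort before cross-validation, mirroring the
reduce-then-classify pipeline order), then runs stratified k-fold
cross-validation at the segment level (default 10 folds, 90/10).
Segment-level folding matches how the study counts performance; it mixes
segments of the same subject across train and test, so a
`subject_level=True` option (group k-fold by subject) provides the honest
generalization test.  Per fold the confusion counts, six metrics and
per-class test MSE against the coded targets are recorded; cell summaries
are unweighted fold means.  Folds that end up single-class are skipped with
a warning and listed in the result.  The whole grid is reproducible from
(config, seed); report CSVs are byte-identical across reruns.

## Numerical choices

* Gaussian-mixture covariances get a relative ridge (1e-6) plus an absolute
  floor; the EM monotonicity assertion allows relative rounding slack 1e-7.
* Exact `Fraction` arithmetic for accuracy/error before percent conversion;
  undefined metrics (zero denominators) are NaN with a warning.
* Mask repair breaks ranking ties by column index (stable sort).
* Degenerate single-class data in the wrapper fitness scores φ = 0 with a
  warning (the parsimony term remains), so mask selection still produces a
  valid 100-column mask for single-subject inputs.
* A perfectly linear DFA profile (constant series) has F(n) = 0 at every
  window: the exponent is undefined and returned as NaN with a warning.
* All randomness flows through `numpy.random.default_rng` seeds; scikit-learn
  components are used only in deterministic configurations.

## Problem sizes in the test suite

The test suite exercises the full 41-subject, 144,000-sample cohort for the
structural counts (segmentation bookkeeping, reduction dimensions) and
scales the learning experiments down to what the properties need: 8-subject,
60-second cohorts for the evaluation grid, 1000-row blob sets for the
classifier sanity suite, 500-row planted-column sets (shift 0.4 per
informative column, so the wrapper fitness does not saturate) for mask
recovery, and 200 Monte-Carlo replicates of length-2000 series for the DFA
exponent calibration.

## Known limitations

* The synthetic cohort is a structural stand-in; absolute accuracy numbers
  on it do not transfer to clinical data, and the default segment-level
  folds share subjects between train and test.
* The firefly/harmony classifiers depend on the class-mean initialization;
  with adversarial multi-modal classes a two-prototype model is simply
  under-parameterized.
* The metaheuristic selectors lean on the class-separation ranking through
  the count repair; with strongly correlated or interacting columns the
  wrapper search at population 20 × 30 iterations explores only a small
  part of the 200-bit mask space.
* Sample entropy on long vectors is O(n²) memory; the descriptor table
  truncates per-subject sequences to 400 values.
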