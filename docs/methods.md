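# Methods

## Signal model

The pipeline assumes a fixed, roughly overhead camera and a static scene
apart from the child: then any pixel whose luminance changes between two
frames belongs (after ROI cropping) to body movement, and the *count* of
changed pixels is a usable movement magnitude.  Two differencing lags are
kept per frame because they respond to different movement speeds: the
1-frame (0.5 s) difference fires only during quick movements, while the
6-frame (3.0 s) difference stays elevated through slow posture drifts and
for the lag span after any event.

### ROI rectification

The bed quadrilateral (corners ordered TL, TR, BR, BL, validated convex)
is mapped to a rectangle by the unique homography through the four
corners, sampled with bilinear interpolation (scikit-image).  For an
axis-aligned rectangle at native size the warp reduces to an exact crop,
which the tests pin down.  The rectified resolution defaults to the
quad's bounding-box size; absolute pixel counts depend on it, but the
per-recording standardization later removes that scale.

### Binarization threshold

Default 30 of 255.  This is a typical luminance-noise floor for consumer
infrared sensors; because features are standardized per recording, the
pipeline is insensitive to the exact value, and it is configurable
everywhere.  "Above the threshold" is strict (`> t`).  No denoising or
morphology is applied to difference images.

### Boundary conventions

Samples whose lagged frame would precede the recording are defined as 0
movement, keeping the movement series aligned 1:1 with frames so epochs
start at samples 1, 61, 121, ….  The 300 s windows look *forward* from
the epoch start (samples n..n+599) and are truncated at the end of the
recording with the actual sample count as denominator — the alternative
(fixed /600 with zero padding) would bias the last nine epochs of every
night downward.  A trailing partial epoch is dropped.

## The six parameters

Formulas are in the README.  Choices that were genuinely open:

* **Variance30** is computed as the population variance of the 60
  combined samples.  The un-normalized "sum of squares minus squared
  mean" variant is available via `variance_30(..., printed_formula=True)`
  for comparison; it is not a variance (it scales with the window length)
  and is not used by default.
* **NonBM threshold k** defaults to ⌈0.001 × ROI area⌉ pixels, tying the
  stillness criterion to resolution; the counter is read at each epoch's
  last sample.  Population (not sample) variance is used throughout; the
  60/59 factor is absorbed by standardization.
* **Standardization scope** is per recording, not per cohort: its purpose
  is to remove between-child body-size and between-night duration
  effects, which only per-night scaling does.  It also keeps
  leave-one-night-out evaluation leak-free, since a held-out night's
  features are computable without the training nights.  Constant columns
  map to zeros.

## Classifier

`ExtraTreesClassifier` with 100 trees, unlimited depth, and all six
features candidate at every split (the ensemble's randomness comes from
its random split thresholds), fixed seed.  No class reweighting is
applied even though Light is roughly half of sleep; an imbalance-aware
variant is a one-line configuration change for users who want it.
Evaluation is leave-one-*night*-out; per-stage metrics are one-vs-rest
accuracy, sensitivity and specificity, with zero-denominator cases
reported as NaN and excluded from the mean ± SD aggregates (sample SD
over folds).  Cohen's kappa is computed from the confusion matrix
marginals.

## Synthetic data

The generator exists because no pediatric sleep-video corpus is public.
It emulates exactly the structure the method exploits, and nothing more:

* **Hypnograms** are sticky Markov chains (stickiness 0.85 per 30 s
  epoch, giving stage runs of a few minutes) whose stationary
  distributions follow age presets — 0–2 years: Wake 7% / Light 45% /
  Deep 18% / REM 30%; 3–6 years: Wake 7% / Light 51% / Deep 22% / REM
  20% — REM higher in infants, Deep somewhat below the ~30% of clinical
  adult scoring.  A linear logit shift (amplitude 0.3) makes Deep more
  likely early in the night and REM late; the amplitude is deliberately
  mild so that no stage ever overtakes Light's plurality at any time of
  night, i.e. elapsed time alone is a weak cue rather than a shortcut.
* **Movement** is a marked point process: within each epoch, bouts
  arrive Poisson at a stage rate and carry log-normal pixel-count
  magnitudes (counts are positive and right-skewed; the pipeline must not
  depend on the family).  The fast channel holds a bout for its duration;
  the slow channel additionally for the 6-sample slow-lag span,
  mimicking how a 3 s difference stays white until the lagged frame has
  passed the event.  Poisson noise (mean 3 px) covers sensor flicker.
  Default rates/magnitudes are calibration choices ordering the stages
  Wake ≫ Light > REM > Deep in mean movement, with Deep nearly silent.
* **Toy video** renders a bright blob over a dark bed making
  stage-conditioned random jumps, so the ingestion → rectification →
  differencing path is testable end to end; a jump of at least one blob
  width changes exactly twice the blob area in pixels, an exact geometric
  oracle.

What the generator does **not** model: real luminance statistics (bedding
texture, lighting drift, camera noise correlation), co-sleeping or
off-bed motion, respiration-scale micro-movement, or any physiological
signal.  Passing the synthetic recovery tests therefore shows the
pipeline's machinery is correct and that it separates stages *whose
movement statistics differ as assumed* — it does not certify accuracy on
real home recordings, where stage-movement separation is far weaker.

## Problem sizes and numerics

The synthetic study runs 8 nights × 900 epochs (7.5 h) per age group —
enough nights for stable leave-one-out folds and enough epochs that
every stage appears in every night.  Rendered-video checks use 8 nights ×
120 epochs at 64×48 px, where differencing dominates runtime.  The
stage-separated cohorts classify at roughly 75% total accuracy (kappa
≈ 0.63–0.67); the stage-independent control sits at kappa ≈ 0.03.  These
figures characterize the controllable synthetic separation, not any real
cohort.  Oracle-equivalence tolerances are 1e-9 relative for feature
formulas and exact for pixel counting; standardization is checked to
1e-9.  Degenerate inputs (constant feature columns, absent stages,
all-zero confusion rows) all have defined behavior covered by tests.

## Known limitations

* The movement→stage link is assumed stationary within a night; real
  children change position relative to the camera.
* No autonomic information: Deep vs REM separation rests entirely on
  movement timing and the epoch index.
* Specificity here is conventional one-vs-rest; published camera-staging
  tables sometimes use other definitions, so cross-paper comparison of
  that column needs care.
* The classifier is epoch-wise; no temporal smoothing or sleep-cycle
  model is applied to the predicted hypnogram.
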