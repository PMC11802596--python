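# Methods

This note documents the models, conventions and design choices behind
`tabkin`, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic experiments do and do not demonstrate.

## Session model

A gameplay session is a five-minute (configurable) recording of free
coloring-game play with the dominant hand. Two streams are modelled:

* **Touch**: timestamped screen points with a phase flag (`down`, `move`,
  `up`) and a pointer id. Sampling is *variable*, nominally ~60 Hz while
  the finger moves. Coordinates are abstract points, origin top-left, y
  down. Timestamps are seconds since session start, written with 6-decimal
  precision (the round-trip precision of the bundle format).
* **IMU**: regular ~20 Hz triaxial user acceleration (m/s², assumed
  gravity-compensated on-device), rotation rate (rad/s) and attitude
  (roll/pitch/yaw, rad).

By default only the first pointer id is analysed (single-finger
dominant-hand play); a switch admits all pointers. Optional touch
pressure/size channels are not part of the format because no feature uses
them.

## Gestures and kinematics

An *atomic gesture* is a down→move…→up run. Segmentation is a linear scan
of phase transitions; an unmatched `down` at stream end closes the gesture
at the last sample with a warning. Gestures with fewer than 3 samples are
retained (they count as gestures and possibly taps) but are excluded from
kinematic aggregates, where derivatives are undefined.

Because sampling is variable, derivatives use actual timestamps and no
resampling: speed between consecutive samples at midpoint times, and
tangential acceleration as the difference quotient of consecutive speeds
over midpoint-to-midpoint intervals. Acceleration is *signed* (derivative
of speed along the path), so its minimum is the deepest deceleration of a
stroke; an unsigned variant is not used. A 3-point moving-average smoother
of the coordinates is available but off by default — the raw sensor
trajectory is the object of study.

A **tap** is a gesture with duration < 0.15 s *and* displacement < 10
points. The capture literature does not pin these thresholds; they are
deliberate, documented defaults, exposed in the extraction config.

## The 269-feature registry

The session representation is a frozen, versioned registry of exactly 269
named features — 105 touch-derived and 164 IMU-derived — built as
{base quantity} × {statistic} grids:

* Touch: 9 per-gesture quantities (duration, path length, displacement,
  hull area, terminal directness, deviation from the chord, mean/max speed,
  inter-gesture pause) × 8 statistics (mean, variance, SD, min, max,
  median, Q1, Q3); 4 extreme-focused quantities (min speed, mean/max/min
  tangential acceleration) × 4 statistics; stroke endpoint coordinates ×
  (mean, SD); and 9 tap/count features (tap count/rate/fraction, gesture
  count, inter-tap interval statistics). Kinematic aggregates run over
  *swipes* (non-tap, non-degenerate gestures); taps are counted, not
  profiled.
* IMU: 4 signals (acceleration, rotation rate, attitude, jerk = first
  difference of acceleration over time) × 4 channels (x, y, z, magnitude)
  × 10 statistics (mean, SD, variance, min, max, range, median, Q1, Q3,
  IQR), plus 4 direction-change rates of acceleration (per-axis
  zero-crossing rates and the mean angular-change rate of the 3-D
  acceleration vector).

Seven features keep canonical names because they drive the group
comparisons: `gesture_area_variance`, `minimum_gesture_acceleration`,
`gesture_directness_variance`, `attitude_variance_x/y`,
`rotation_variance_x`, `accel_direction_change_rate_y`.

Definitions where several readings are defensible:

* **Gesture area** — area of the convex hull of the stroke's points
  (Qhull); 0 for collinear or < 3 distinct points.
* **Directness** — displacement / path length of the *terminal* quarter of
  the stroke's samples (`tail_fraction` = 0.25; "final data points" is not
  otherwise quantified). A stationary tail has directness 1. The session
  feature is the population variance of per-gesture directness.
* **Minimum gesture acceleration** — session mean of per-gesture minimum
  tangential acceleration.
* **Deviation from a straight line** — maximum perpendicular distance from
  the start→end chord (the area-between-curves alternative is noted but
  not implemented).
* **Acceleration direction-change rate** — sign changes of the axis
  component per second (robust to discretization); the 3-D variant uses
  the mean absolute angular velocity of the acceleration vector.

Conventions: all variances and SDs are population (divide by N); quartiles
interpolate linearly between order statistics; aggregates of an empty set
are NaN — an explicit missing-value sentinel that propagates to the
feature table (empty CSV cells), never a silent zero. Count features of an
empty session are 0.

## Per-movement profiles

Each swipe's speed and tangential-acceleration series are time-normalized
to [0, 1] over the gesture (samples at their midpoint timestamps), split
into `n_bins` left-closed bins (last bin closed; default `n_bins` = 10, a
tunable hyperparameter), and summarized per bin by mean, median, SD, Q1,
Q3. Occupancy counts per bin sum to the series length; empty bins are
imputed with the gesture-level statistic and flagged. Each movement is one
training sample that inherits its session's subject id and group label, so
splits can keep all of a subject's movements together.

## Classifiers

* **Session network**: two hidden ReLU layers (20–40 units), softmax
  output, weighted cross-entropy, full-batch Adam with β₁ = 0.95,
  β₂ = 0.99 and inverse-scaling learning rate `lr_t = lr₀/√t`
  (lr₀ ∈ [0.001, 0.01]); epoch cap 500 with early stop on a training-loss
  plateau. The network is implemented directly (numpy) because the
  training recipe requires per-class weights and this optimiser/schedule
  combination, and because bit-determinism under a seed is part of the
  evaluation contract. Full-batch training is appropriate at cohort sizes
  of tens of subjects.
* **Profile GBM**: scikit-learn gradient boosting — 500–1000 trees,
  learning rate 0.1, subsample 0.8, depth 2, log2(feature count) features
  per split. A session's prediction is the arithmetic mean of its
  movements' probability vectors (argmax decides the class); averaging
  commutes with permutation of the movements.
* **Class weights**: balanced inverse frequency `w_c = N/(K·N_c)` computed
  per classified pair/triple on the training fold — larger groups weigh
  less than 1.
* **Grid search**: exhaustive over the configured ranges (units
  {20, 30, 40} × lr {0.01, 0.003, 0.001}; trees {500, 1000}); best mean
  validation accuracy, ties broken toward the smaller model, then the
  lower learning rate; the full score table is returned.

## Validation and statistics

Cross-validation partitions *subjects*: leave-one-out; repeated stratified
k-fold (n_folds is a hyperparameter, default 4; 10 repeats; data
reshuffled before each repeat); and a nested variant whose inner loop
tunes the grid on training subjects only. Feature standardization (mean 0,
SD 1) is fitted on the training fold and applied to the held-out fold;
zero-SD features map to 0 with a warning; NaN sentinels are imputed at the
training mean. A leakage guard raises if any subject appears on both sides
of a split; training folds missing a class are skipped with a warning.
Confusion matrices pool predictions over folds and repeats (row sums =
group sizes × repeats; leave-one-out counts each subject exactly once).

`confusion_metrics` reports accuracy (trace/total), sensitivity and
specificity for a designated positive class (two-class case), and the
above-chance gain (accuracy − 1/K)/(1/K) in two conventions: from the
exact accuracy, and with accuracy and chance first rounded to whole
percents — headline figures quoted as rounded percentages are only
reproduced by the second convention (e.g. 31/54 correct → 57%, and
(57 − 33)/33 ≈ 73% above chance, versus 72.2% unrounded).

Feature screening: each feature is tested per group for normality with a
Kolmogorov–Smirnov test against a normal with estimated parameters
(Lilliefors, α = 0.05; Shapiro–Wilk selectable). Features normal in every
group use one-way ANOVA (all groups) and independent t-tests (pairs); all
others use Kruskal–Wallis and Mann–Whitney U. Raw p-values are reported by
default, mirroring how such screens are usually tabled;
Benjamini–Hochberg-adjusted columns are available behind a flag.
Feature–covariate association uses Kendall's τ-b (tie-corrected, robust to
extreme values), across all subjects and within groups.

## Synthetic cohorts

The generator's role is to provide data with the statistical structure the
analysis assumes, with one controlling knob per group-comparison feature.

* **Swipes** follow a minimum-jerk arc-length profile
  `s(u) = L(10u³ − 15u⁴ + 6u⁵)`, whose tangential acceleration has the
  closed-form minimum `−(10/√3)·L/T²`. Each swipe draws its deceleration
  floor from `N(decel_floor_mean, decel_floor_sd)` and solves for the
  duration that realizes it, so the knob maps onto the extracted minimum
  tangential acceleration up to discretization. A perpendicular
  half-sine bow with lognormal amplitude (σ = `area_log_sd`, scaled by the
  touch noise scale) gives strokes their hull area; a tapered sinusoid
  over the final quarter (half-normal amplitude `directness_tail_sd`)
  perturbs terminal directness. Sample times jitter uniformly ±20% around
  1/60 s. Taps last 0.04–0.10 s with ≲3-point displacement. Inter-gesture
  pauses are exponential with mean chosen to hit the archetype's gesture
  rate; with the default 0.5 gestures/s a 300 s session holds ~150
  gestures.
* **IMU channels** are stationary AR(1) processes with archetype-set
  marginal SDs (attitude ρ = 0.95, rotation ρ = 0.8, acceleration
  ρ = 0.6), plus small gesture-locked perturbations (exponential-decay
  kicks on acceleration/rotation, a damped oscillation on attitude) that
  tie device motion to touch activity. The y-acceleration AR coefficient
  is `ρ = cos(π·r/f_s)`, which makes its zero-crossing rate equal the
  archetype's direction-change-rate target `r`.
* **Presets**: TD is the baseline archetype. ASD elevates attitude x/y and
  rotation x dispersion, deepens the deceleration floor, raises hull-area
  dispersion and the y direction-change rate; DCD triples the terminal
  perturbation and lowers the y direction-change rate. These reproduce the
  designed pairwise significance pattern of the seven comparison features.
  Effect levels: `large` (default), `medium` (half offsets), `none`
  (exchangeable null cohort). Because the source study reports only
  p-values, not effect sizes, the presets are calibrated to the
  significance *pattern*, not to clinical effect magnitudes — synthetic
  classification accuracies are therefore not comparable to accuracies on
  real cohorts.
* **Determinism**: a cohort is a pure function of its spec; per-subject
  seeds derive from the master seed via counter-based spawn keys, so
  enlarging a cohort never changes existing subjects. Subject covariates
  (a motor-battery-like standard score, age) are drawn from group-specific
  normals so covariate-correlation machinery is exercisable.

What the generator does **not** emulate: picture content and tool/color
choices, two-handed or off-hand touches, device pickup artifacts, gravity
leakage into user acceleration, drift or dropout in either sensor, and any
true covariance structure between touch style and device motion beyond the
gesture-locked kicks. Passing recovery tests therefore demonstrates that
the pipeline measures what the knobs control — not that real cohorts
separate.

## Experiment sizes and numerical choices

The packaged experiments use 20 subjects per group and 5-minute sessions —
the scale of a typical single-site clinical cohort. Parameter recovery
(seed 1) checks the seven designed pairwise differences at p < 0.05 and
pairwise leave-one-out accuracies; null calibration pools 10 exchangeable
cohorts (600 predictions) for the 3-way accuracy band around 1/3, and
1000 simulated null features for the type-I band around α = 0.05.

Degenerate inputs are handled explicitly: duplicate timestamps within a
gesture raise an error naming the gesture; empty IMU streams yield NaN
sentinels with a warning; all-constant features are skipped and flagged in
the test report; τ on a constant vector is flagged undefined. Hull
computation falls back to area 0 on degenerate (collinear) geometry.

## Known limitations

* The 269-feature inventory is a reconstruction: the source feature list
  is not published, so the registry fixes a defensible grid with the seven
  comparison features mapped explicitly; counts (105/164/269) are enforced
  by test.
* Sensitivity/specificity in two-class reports depend on the designated
  positive class (default: the second-listed group of the pair).
* The normality-gated router is slightly conservative on the ANOVA branch
  and slightly anticonservative on the nonparametric branch (selection by
  the gate); its *pooled* type-I rate is calibrated, which is what the
  null experiment checks.
* Leave-one-out accuracy on near-chance problems is pessimistically biased
  with class-weighted training; null calibration therefore uses k-fold.
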