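# Methods

## Problem and pipeline

`throwsense` turns raw recordings from a wrist-worn 9-DoF IMU into throw-level
workload quantities for team handball: how many throws a player made, what
kind (approach: standing / running / jumping; wind-up: circular / whip-like),
and how fast each ball left the hand.  The pipeline has five stages, each a
module with a narrow contract:

1. **imu_io** — read delimited multi-rate recordings and linearly resample
   each feature-bearing channel onto an exactly uniform grid: 1150 Hz for the
   low-g accelerometer (±16 g, nominal 1125 Hz) and gyroscope (±2000 °/s,
   nominal 1125 Hz), 1600 Hz for the high-g accelerometer (±200 g).  The
   slight super-nominal gyro/low-g target absorbs the sampling-frequency
   fluctuation of the hardware.  The grid is anchored at the first input
   timestamp and never extrapolates; non-finite samples are dropped per
   sensor before interpolation, so gaps are bridged linearly and explicitly.
2. **throw_detection** — a throw is a supra-threshold excursion of the
   gyroscope y-axis, default threshold 1500 °/s.  Each contiguous run of
   samples at or above threshold contributes one candidate at its maximum;
   candidates closer than 1 s merge, keeping the larger peak (two handball
   throws cannot recur faster, and the refractory merge suppresses the
   oscillatory shoulder of a single throw).  Windows of 2, 3, 4 and 6 s are
   cut per sensor, temporally centered on the peak-rotation instant; the
   high-g excerpt is located by time, not shared index, because rates differ.
   Windows that would cross a recording boundary are discarded, not padded —
   padding corrupts moment and spectral statistics.
3. **feature_extraction** — 201 features per throw per window: 16 statistics
   on each of 12 channels (3 sensors × {x, y, z, vector magnitude}) plus 3
   between-axis Pearson correlations per sensor (3 × 4 × 16 + 3 × 3 = 201).
   The statistic set {mean, sum, sd, variance, cv, min, max, peak-to-peak
   amplitude, iqr, skewness, excess kurtosis, power, rms, lag-1
   autocorrelation, dominant frequency, spectral entropy} covers every
   statistic family the analysis names while reproducing the 201 count
   exactly; the catalogue is versioned so alternative enumerations can be
   swapped in.  Definitions: sd/variance use ddof = 1; skewness and kurtosis
   are Fisher moment ratios without bias correction; cv = sd/|mean| with 0
   when |mean| < 1e-12; power is the mean of squares; dominant frequency is
   the argmax of the mean-removed periodogram excluding the zero bin;
   spectral entropy is the Shannon entropy of the normalised periodogram
   divided by log(#bins), so it lives in [0, 1].  On a degenerate (constant)
   channel cv, skewness, kurtosis, lag-1 autocorrelation, dominant frequency
   and spectral entropy are all defined as 0, keeping every vector finite.
   cv is additionally capped at 100: gyroscope axes are near-zero-mean, so
   the raw sd/|mean| ratio is heavy-tailed — a single window whose mean sits
   in the noise can otherwise standardize to a z-score in the hundreds and
   send a polynomial-kernel prediction off to absurd values for a whole
   held-out subject.  The cap is scale-invariant and far above any
   stable-regime cv.
4. **modeling** — four families (RF, linear SVM, polynomial SVM, GBM) for
   approach/wind-up classification and velocity regression, each on the
   high-g feature set (gyro + high-g accelerometer, 134 columns) and the
   low-g set (gyro + low-g accelerometer, 134 columns) separately.  Inside
   every leave-one-subject-out fold: greedy correlation pruning at |r| > 0.95
   (drop, from the worst pair, the member with the larger mean absolute
   correlation; ties drop the later column), z-standardization with training
   parameters, hyperparameter tuning by seeded 10-fold CV (stratified for
   classification), fit, and prediction of the held-out subject.  Fitting
   preprocessing inside the fold prevents the held-out subject leaking into
   pruning or scaling; a `global_preprocess` switch reproduces the pooled
   alternative.  Metrics are one-vs-rest sensitivity, specificity, balanced
   accuracy and F1 per class, and MAE / RMSE / MAPE for regression.
   Permutation importance permutes one column at a time (mean score drop over
   repetitions, negatives clipped, scaled so the top feature is 100).
5. **stats_compare** — per-subject fold metrics feed a balanced two-way
   fully-within-subject ANOVA (model family × measurement range).  Each
   effect is tested against its own subject-by-effect error term; the
   Greenhouse–Geisser epsilon (Box sample-covariance estimator on orthonormal
   contrast scores, bounded to [1/df, 1]) multiplies both degrees of freedom
   before the p-value.  Range contrasts are paired within-subject differences
   per stratum — identical to estimated-marginal-means contrasts under the
   balanced design — with step-down Holm adjustment across strata.  Alpha is
   0.05 throughout.

## The synthetic study generator

No public recording of this kind exists, so the `synthetic_data` module is a
first-class, tested component that emulates the study design the analysis
assumes: 17 subjects, 6 conditions (3 approaches × 2 wind-ups), 7–10 throws
per condition per subject (so 42–60 per subject), throws ≥ 8 s apart, and
per-condition radar velocities drawn from Normals — standing 20.7 ± 2.6
(circle) / 20.1 ± 2.5 (whip), running 22.0 ± 2.4 / 21.2 ± 2.4, jumping
21.4 ± 2.5 / 21.0 ± 2.4 m/s — truncated at ±2σ.  Sensors run at their
nominal rates with 2 % per-interval timestamp jitter so resampling is
genuinely exercised, and carry additive Gaussian noise (0.02 g low-g,
0.08 g high-g, 8 °/s gyro).

Per throw, with velocity v and a per-subject multiplicative gain
(~N(1, 0.02), truncated):

* gyro-y: a 0.3 s raised-cosine pulse, peak = 90 °/s per m/s ×
  (v + ε_shared + ε_gyro), floored at 1650 °/s.  ε_shared ~ N(0, 0.9²) is the
  shared signal-to-velocity measurement noise; ε_gyro ~ N(0, 0.8²) is extra
  gyro-only encoding noise.  The floor guarantees every synthetic throw
  clears the 1500 °/s detection threshold (typical peaks are 1800–2000 °/s),
  which is what makes detection closure an exact property rather than a
  statistical one; the cost is a flattened lower tail in the gyro's velocity
  encoding, which only reinforces the accelerometer's advantage.
* gyro-x: the wind-up signature — one broad 0.6 s lobe (circular) versus a
  sharp 0.15 s biphasic cycle (whip-like).  Circular wind-ups thus have a
  large positive gyro-x integral and whips a near-zero one, so means and sums
  of gyro-x separate the two, matching the kind of feature the classification
  task is expected to lean on.
* accelerometer x/y: an impact-like *flat-top spike* — a fixed 0.12 s
  raised-cosine rise envelope (60 g) capped at an apex of 1.1 g per m/s ×
  (v + ε_shared + ε_acc), ε_acc ~ N(0, 0.2²), the y apex at 0.8× the x apex.
  The rise profile is limb-speed-limited and identical across throws; only
  the apex height encodes velocity.  The low-g channel clips at ±16 g, below
  the apex of essentially every throw, so its clipped view of the spike is
  the same waveform regardless of velocity: the information is destroyed,
  not merely transformed.  (An earlier design scaled the whole pulse with
  velocity, but clipping a globally-scaled smooth pulse is an invertible
  transform — the sub-clip wings still encode the amplitude — and the low-g
  set lost nothing.  The flat-top construction is what makes measurement
  range matter in the way the analysis is designed to detect.)
* accelerometer z: the approach signature — quiet for standing, a 0.5 g
  2.5 Hz oscillation for the 2 s before a running throw, and a near-
  weightless 0.45 s flight phase followed by an 8 g landing spike for
  jumping.

Consequences of this design, which the tests verify: detection precision and
recall are exactly 1.0 at 0.1 s tolerance; approach and wind-up are almost
perfectly classifiable (the signatures are far above the noise floor, so the
≥ 0.90 balanced-accuracy requirement has a wide margin); the best attainable
velocity error is the shared-noise floor, MAE = 0.9·√(2/π) ≈ 0.72 m/s, and
the LOSO regressor is required to stay within twice that; and the high-g set
beats the low-g set at regression because the low-g set must fall back on
the noisier gyro encoding (observed gap ≈ 0.1–0.2 m/s, the same direction
and order as the motivating comparison).

What the generator does *not* emulate: biomechanical waveform realism,
inter-throw variability of pulse shapes, magnetometer content, soft sensor
nonlinearity, or class overlap from imperfect technique.  Passing tests
therefore demonstrate that the pipeline's machinery is correct and honest
(no leakage, right arithmetic, recoverable parameters under its stated
noise model) — not that real-data accuracies would reach any particular
level.

## Numerical and design choices

* Resampling grid: `floor(span × rate + 1e-9) + 1` points — the epsilon keeps
  the final sample when the input already lies on the target grid, making
  resampling idempotent to 1e-12.
* Detection thresholds the *signed* gyro-y by default (`use_abs` available):
  which convention the original hardware used is unknowable from the text,
  and signed is the stricter reading.
* Run maxima take the first index on exact ties (deterministic).
* Correlation pruning treats constant columns as r = 0 against everything
  and flags them rather than removing them.
* Tuning score ties resolve to the earlier grid point; a single-point grid
  skips CV entirely (used by the fast acceptance settings).
* Default grids are small and standard: RF 500 trees × mtry {√p, p/3};
  SVM C {0.1, 1, 10} (× degree {2, 3} for the polynomial kernel); GBM
  trees {100, 300} × depth {2, 3} × learning rate {0.05, 0.1}.  The
  polynomial kernel is the inhomogeneous form (coef0 = 1): the homogeneous
  kernel is ill-conditioned on standardized features and can diverge badly
  in regression.
* The GG epsilon for a 2-level factor is exactly 1; the F statistic is never
  changed by the correction, only its reference distribution.
* Holm is the step-down max-accumulation form, monotone by construction.
* Problem sizes in the test suite and acceptance script: the full 17-subject
  study is simulated once with 2 s and 3 s windows (the two sizes the
  headline results use), classification uses a single-point GBM
  (100 trees, depth 3) and regression a single-point linear SVM (C = 10) —
  desk-scale settings chosen so the whole analysis reruns in minutes while
  leaving every tested margin wide.

## Known limitations

* The exact 201-feature enumeration of the original analysis is unpublished;
  the catalogue here is one consistent, versioned reconstruction.
* "Power" is read as mean square; band-power or total-energy readings would
  scale some features but not change any pipeline property.
* Permutation importance stands in for the ambiguous "with and without each
  feature" description; a refit-based leave-one-covariate-out variant would
  be slower and may rank correlated features differently.
* The ANOVA assumes exactly one response per subject per cell (the
  per-subject LOSO fold metric); nesting multiple iterations per cell would
  require a mixed model, which is out of scope.
* Real-data accuracy figures cannot be reproduced here because the original
  recordings are private; only arithmetic identities and synthetic
  direction-of-effect checks are meaningful.
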