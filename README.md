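# throwsense

Throw-event detection, signal-feature extraction and workload modeling for
wrist-worn IMU recordings in team handball.

Monitoring throwing workload in handball is hard: counting throws by hand is
impractical, and neither throw count, type, nor intensity is visible to
GPS-style tracking.  A wrist-mounted 9-DoF inertial unit — low-g
accelerometer (±16 g), high-g accelerometer (±200 g), gyroscope
(±2000 °/s) — captures each throw as a violent rotation burst.  `throwsense`
implements the full analysis chain from raw multi-rate recordings to
throw-level workload estimates:

* **Detection** — throws are supra-threshold excursions of the gyroscope
  y-axis (|ω_y| crossing 1500 °/s), one event per excursion at its peak,
  with a 1 s refractory merge.
* **Features** — for windows of 2, 3, 4 and 6 s centered on the peak
  rotation, 201 features: 16 statistics (mean, sum, sd, variance, cv, min,
  max, amplitude, iqr, skewness, kurtosis, power, rms, lag-1 autocorrelation,
  dominant frequency, spectral entropy) on each of 12 channels
  (3 sensors × {x, y, z, √(x²+y²+z²)}) plus 3 between-axis correlations per
  sensor.
* **Modeling** — RF, linear SVM, polynomial SVM and GBM classify the
  approach (standing / running / jumping) and wind-up (circular /
  whip-like) and regress peak ball velocity (m/s), separately on the high-g
  feature set (gyro + high-g accelerometer) and the low-g set.  Evaluation
  is leave-one-subject-out (LOSO): each subject is predicted by a model that
  never saw them, with correlation pruning (|r| > 0.95), standardization and
  10-fold hyperparameter tuning refit inside every fold.  Metrics:
  per-class sensitivity / specificity / balanced accuracy / F1, and
  MAE / RMSE / MAPE; permutation importance scaled to 0–100.
* **Comparison** — per-subject fold metrics feed a two-way repeated-measures
  ANOVA (model family × measurement range) with Greenhouse–Geisser-corrected
  degrees of freedom, and paired high-g vs low-g contrasts with Holm
  adjustment.
* **Simulation** — a seeded generator produces full synthetic studies
  (17 subjects, 6 conditions, 7–10 throws each, condition-specific velocity
  distributions, saturating low-g channel, timestamp jitter) with ground
  truth, so every stage is testable without any private data.

See `docs/methods.md` for the model details and the generator's assumptions.

## Worked example

```python
import numpy as np
from throwsense.synthetic_data import SimulationConfig, simulate_study
from throwsense.pipeline import featurize_study
from throwsense.feature_extraction import split_range_sets
from throwsense.modeling import ModelSpec, loso_evaluate

cfg = SimulationConfig(n_subjects=4, throws_per_condition=(3, 3), seed=7)
sessions, truth = simulate_study(cfg)
fm = featurize_study(sessions, window_sizes_s=(2.0, 3.0))

high, low = split_range_sets(fm)          # 134 feature columns each
fm3 = high[high["window_s"] == 3.0].reset_index(drop=True)

spec = ModelSpec("GBM", "classify_approach",
                 grid={"n_estimators": [100], "max_depth": [3],
                       "learning_rate": [0.1]}, seed=1)
res = loso_evaluate(spec, fm3)
print({c: round(m["balanced_accuracy"], 3) for c, m in res.metrics.items()})
```

prints

```
{'jumping': 1.0, 'running': 1.0, 'standing': 1.0}
```

— on this small synthetic study the approach signatures (running cadence,
jump flight/landing) are far above the sensor noise floor, so the
gradient-boosting classifier separates all three approach types perfectly in
LOSO evaluation.  Velocity regression on the same study
(`ModelSpec("SVM_L", "regress_velocity", grid={"C": [10.0]})` on the 2 s
window) gives MAE ≈ 1.04 m/s with the high-g set and ≈ 1.82 m/s with the
saturating low-g set: the ±16 g channel clips during the throw impact, so
velocity must be recovered from the noisier gyroscope encoding.  At the full
17-subject design these errors drop to ≈ 0.70 and ≈ 0.89 m/s (see below).

The same stages are available from the shell:

```
throwsense simulate --n-subjects 3 --seed 7 --out sessions/
throwsense detect --in sessions/S01.csv --out events.csv
throwsense featurize --in sessions/S01.csv --truth sessions/truth.csv \
    --subject S01 --out features.csv
throwsense compare --metrics per_subject_mae.csv --out stats/
```

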