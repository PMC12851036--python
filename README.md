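# gazestrain

Gaze decoding from wearable eyelid strain sensors, and digital strabismus
diagnosis built on it.

Strabismus care needs two measurements at once: the deviation angle and the
function of the six extraocular muscles. Clinically both come from
instrument-heavy, partly subjective tests (prism-cover, Hess screen). A
skin-like strain-sensing array worn on the upper eyelid offers an objective
alternative: eye movements deform the eyelid, the deformation is transduced
linearly into a relative resistance change (ΔR/R = 0.169·ε, |ε| ≤ 15 %), and
the direction-dependent polarity and amplitude of three sensing units
(0°/45°/90°) encode gaze direction and angle. This package implements the
full computational stack for researchers working on such systems:

* **`gazestrain.simulate`** — a seeded generator of 3-channel eyelid-strain
  recordings with the physiological structure the decoder assumes: upward
  gaze → negative 90°-unit signal, horizontal gaze → 0°-unit signal with
  adduction/abduction polarity, peak strain linear in gaze angle up to 18°
  (≤ 4 % looking down, ≤ 11 % otherwise), saccade–hold–return morphology,
  baseline wander, noise, blink and facial-expression artifacts, and
  per-subject coupling differences.
* **`gazestrain.preprocess`** — zero-phase 0.5 Hz high-pass, per-event
  segmentation, expansion to the 10-channel differential representation
  (3 raw + 3 channel differences + 3 lag-1 differences + 1 long-lag mean
  difference), robust channel scaling.
* **`gazestrain.models`** — the lightweight two-depth InceptionTime-style
  classifier (bottleneck + kernels 17/7/3 + max-pool branch, 32 filters per
  branch; exactly 65,156 trainable parameters for 4 classes), per-direction
  MLP angle regressors (10 → 256 → 128 → 64 → 1; exactly 44,033 parameters),
  a signal-polarity rule baseline, a KNN-DTW baseline, and few-shot subject
  calibration (2–5 windows per position). Classifier and regressors are
  sklearn-style estimators; the training stack (conv/batch-norm/pooling
  layers, Adam, cosine decay) is implemented in numpy inside the package.
* **`gazestrain.hess`** — the digitized Hess screen test: tangent-plane chart
  geometry (5° per grid square at 0.5 m), nine cardinal positions at ±15°,
  chart construction from repeated decoded gaze points, the symmetry / size /
  position diagnosis rules with paretic-muscle localization, and
  cover–uncover interpretation.
* **`gazestrain.agreement`** — ICC(A,1) with F-based 95 % CI, Bland–Altman
  bias and limits of agreement, folded-ECDF (mountain) plots, stratified
  tables.

## Worked example

Train the decoder on a simulated cohort and diagnose a synthetic medial
rectus palsy:

```python
import numpy as np
from gazestrain import (
    ChannelScaler, InceptionTimeTinyClassifier, MLPAngleRegressor,
    extract_regression_features, make_gaze_dataset,
)

X, labels, angles, _ = make_gaze_dataset(n_windows=2000, n_subjects=4, seed=0)
scaler = ChannelScaler().fit(X[:1000])
Xs = scaler.transform(X).astype(np.float32)

clf = InceptionTimeTinyClassifier(epochs=20, random_state=0).fit(Xs[:1000], labels[:1000])
accuracy = (clf.predict(Xs[1000:]) == labels[1000:]).mean()

feats = extract_regression_features(Xs)
errors = []
for c in np.unique(labels):
    tr = np.flatnonzero(labels[:1000] == c)
    te = np.flatnonzero(labels[1000:] == c) + 1000
    reg = MLPAngleRegressor(random_state=0).fit(feats[tr], angles[tr])
    errors.append(np.abs(reg.predict(feats[te]) - angles[te]))
print(f"direction accuracy: {accuracy:.3f}")
print(f"angle MAE: {np.concatenate(errors).mean():.2f} deg")
```

```
direction accuracy: 1.000
angle MAE: 1.97 deg
```

A held-out direction accuracy of 1.000 means the classifier recovers the gaze
direction from signal polarity and morphology perfectly at the default noise
level on this 2,000-window cohort; an angle MAE of 1.97° is the mean absolute
error of the per-direction angle regressors over 5°–20° movements (it drops to
~1.6° on the larger 5,000-window benchmark the test suite runs).

```python
from gazestrain import diagnose, synthetic_palsy_chart

left, right = synthetic_palsy_chart("medial rectus", eye="right")
report = diagnose(left, right)
print(report.paralytic, report.paretic_eye,
      report.horizontal_deviation, report.implicated_muscles)
```

```
True right exo ['medial rectus']
```

The right chart is smaller and shifted temporally with its largest
underaction in adduction, so the rule engine reads paralytic strabismus of
the right eye, exotropia, medial rectus palsy.

The same pipeline is scriptable from the shell:

```bash
gazestrain simulate --out runs/sim --seed 0 --n-events 20
gazestrain train --out runs/train --seed 0 --n-windows 600
gazestrain evaluate --model runs/train/model.npz --out runs/eval --seed 1
gazestrain calibrate --model runs/train/model.npz --out runs/cal --seed 2 --n-samples 3
gazestrain diagnose --left left.json --right right.json --out runs/dx
gazestrain agree --data pairs.csv --out runs/agree --by sex
```

Every run directory receives the resolved configuration, package versions and
a log, so results can be reproduced exactly.

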