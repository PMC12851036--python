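# Methods

`gazestrain` implements the computational stack of a wearable eyelid-strain
gaze-decoding system: a biophysically structured signal simulator, a
preprocessing pipeline, a lightweight 1-D convolutional direction classifier
with per-direction angle regressors, a rule-based digitization of the Hess
screen test, and method-agreement statistics. This note documents the models,
their assumptions, the tunable parameters, and the numerical choices.

## Signal model

A resistive strain gauge on the upper eyelid transduces eyelid strain ε into a
relative resistance change linearly, ΔR/R = k·ε, with gauge factor k = 0.169
and a measurement range of |ε| ≤ 15 % (simulated strain beyond the range
saturates, as a physical gauge would). Three sensing units are oriented at
0°, 45° and 90° on the lid; channel order is always (0°, 45°, 90°).

Gaze excursions couple into eyelid strain with direction-dependent polarity:

* upward gaze compresses the upper eyelid → negative 90°-unit signal; downward
  gaze stretches it → positive;
* horizontal gaze drives the 0° unit, with adduction (toward the nose)
  negative and abduction positive — spatial left/right therefore resolve
  through the side of the sensed eye;
* the off-axis unit retains a residual coupling of 5 % of the dominant unit's
  gain ("barely any signal"); the 45° unit couples to both axes at 0.6 × the
  dominant gain, so vertical and horizontal strains can partially cancel on it
  for some oblique directions.

During the hold phase of an event at gaze angle θ the strain on unit *u* is
`unit_gain[u] · (θ / 18°) · ε_max`, linear in angle up to the 18° reference
angle (and extrapolated linearly to the 20° amplitude ceiling), with
ε_max = 4 % for downward gaze and 11 % for all other directions. Oblique
directions combine the two adjacent cardinal priors vectorially (divided by
√2) and renormalize.

Events have a raised-cosine saccade ramp (default 0.15 s), a hold, and a
raised-cosine return. Recordings add, per channel: a sinusoidal baseline
wander below 0.5 Hz (default amplitude 0.002 ΔR/R at 0.25 Hz with random
phase), white Gaussian measurement noise (default SD 0.001 ΔR/R), and
optionally blink (0.3 s biphasic pulse, ~1.5 × the largest directional
amplitude, same polarity on both axis units — a pattern no gaze direction
produces) and facial-expression artifacts (1–2 s smooth multi-channel
waveforms). All randomness flows from one integer seed.

**Hold durations and the high-pass filter.** The pipeline's 0.5 Hz
zero-phase 4th-order Butterworth high-pass attenuates plateaus longer than
roughly 0.45 s below their own filter rebound, inverting the apparent signal
polarity. Only the fast end of the 0.1–1 Hz movement band is therefore
observable through this filter, and the generator defaults to hold durations
of 0.25–0.40 s. This is a property of the stated filter, not of the gauge.

**Cohorts.** Subjects differ by a multiplicative overall gain (N(1, jitter),
default jitter 0.1), per-unit gains (N(1, jitter/2)), a baseline offset, and
optionally per-direction gain multipliers modelling direction-specific eyelid
mechanics. Stratification attributes (age group, sex, eyelid phenotype) are
drawn uniformly and carried in `subject_meta`.

**What the simulator does not emulate.** Real recordings contain attachment
drift, skin-hydration trends, head-movement crosstalk, non-stationary noise
and richer inter-session variability. Passing benchmarks on this generator
shows the pipeline recovers the structure the generator encodes — polarity,
angle-amplitude monotonicity, artifact morphology — not clinical performance.

## Preprocessing

1. High-pass filter, 4th-order Butterworth at 0.5 Hz, applied
   forward-backward (zero phase) to the full recording before segmentation.
2. Segmentation into 2.0 s windows centered on each annotated event onset;
   windows clipped by a recording edge are dropped.
3. Expansion to 10 channels: the 3 raw unit signals; the 3 pairwise channel
   differences (s0−s45, s45−s90, s0−s90); the 3 lag-1 time differences
   (zero-padded at the first sample); and the lag-K difference of the channel
   mean with K = round(0.2 s × fs), capturing a longer deformation timescale.
4. Channel-wise division by a robust per-channel scale (99th percentile of
   |x| over the training windows). No centering anywhere: signal polarity is
   the physiology the classifier exploits.

## Direction classifier

A two-depth InceptionTime-style network sized for wearable deployment. Each
block applies a kernel-1 bottleneck (to 32 channels), three parallel
length-preserving convolutions with kernels 17/7/3 from the bottleneck
output, and a stride-1 max-pool branch followed by a kernel-1 convolution;
the four 32-channel branches concatenate to 128 channels, followed by affine
batch normalization and ReLU. Convolutions carry no biases. After the second
block: global average pooling over time and an affine map to the class
logits. No residual shortcuts (the canonical shortcut appears every third
block; depth 2 never reaches one). The 4-class network has exactly 65,156
trainable parameters (~254 kB at 32-bit); a 9-class head gives 65,801.

Training: Adam, initial learning rate 10⁻³ with cosine decay over 20 epochs,
batch size 64, softmax cross-entropy, seeded shuffling. The whole stack
(layers, backward passes, Adam) is implemented in numpy inside the package;
gradients are verified against central finite differences in the test suite,
and training is bit-reproducible for a fixed seed on one BLAS thread.

Baselines: a polarity rule (sign of the dominant 0°/90°-unit extremum, with a
0.002 ΔR/R uncertainty threshold) and KNN with multichannel dynamic time
warping (unconstrained warping, absolute-difference local cost, per-channel
costs summed; majority vote with distance tie-break).

## Angle regression

One MLP per direction class, input = the 10 signed channel extrema of the
expanded window, hidden layers 256/128/64 with ReLU and dropout 0.2 after
each hidden activation, scalar angle output (44,033 parameters, ~172 kB);
a 2-D gaze-point output variant (44,098 parameters) minimizes the Euclidean
distance loss instead of squared error. Regressors are fitted only on their
own class's samples and routed by the predicted class at inference; the
blink/expression class routes to no regressor. Regressor training uses 300
epochs by default — the 10-dimensional feature space makes epochs cheap, and
the squared-error loss needs the longer schedule to converge.

## Few-shot subject calibration

Given 2–5 labeled windows per cardinal position from a new subject,
calibration returns an adapted copy (the original models are untouched):

* the classifier is fine-tuned end to end at 0.1 × the base learning rate for
  20 epochs (batch statistics also adapt);
* each per-class regressor is fine-tuned the same way (200 epochs), and then
  a per-class affine output recalibration is fitted by ordinary least squares
  on the calibration samples (slope clipped to [0.5, 2]).

The affine recalibration is deliberately low-capacity: an over-parameterized
fine-tune tends toward interpolating the calibration windows, so its error
does not shrink as samples accumulate, whereas the two-parameter least-squares
fit averages calibration noise with variance ∝ 1/n. This is what produces the
clinically expected behaviour that more calibration samples give a better
adapted model.

## Hess screen digitization

Chart coordinates are gaze angles in degrees (+x toward the patient's right,
+y up); the physical screen maps angles to meters by a tangent projection at
0.5 m viewing distance where one 5° grid square subtends 5°. The chart holds
the 3×3 grid of cardinal positions at 0°/±15° (position 1 central, 2–9
clockwise from straight up); measured points are means over repeats (six in
the clinical protocol) with an RMS dispersion recorded.

Diagnosis reads the paired charts in the clinical symmetry/size/position
order, with all thresholds exposed in configuration:

1. **symmetry** — chart area (shoelace over the 8 outer measured points
   ordered by bearing; the undeviated chart covers 900 deg²) ratio below 0.85
   marks paralytic strabismus;
2. **size** — the smaller chart's eye is paretic;
3. **position** — the mean measured-minus-target shift of the deviating eye,
   thresholded at 2°, maps to eso/exo through the eye's nasal/temporal sides
   and to hyper/hypo vertically;
4. **muscle** — the position of maximal underaction (projected shortfall of
   the measured excursion along the center→target direction) on the paretic
   eye selects the muscle whose action field contains it: adduction → medial
   rectus, abduction → lateral rectus, elevation in abduction → superior
   rectus, elevation in adduction → inferior oblique, depression in abduction
   → inferior rectus, depression in adduction → superior oblique. Pure
   elevation/depression positions are assigned to the vertical recti, whose
   action fields span the vertical midline; every outer position maps to
   exactly one muscle per eye. Only single-muscle localization is automated;
   the ranked underaction table accompanies the report for complex patterns.

Synthetic reference charts for each single-muscle palsy (graded excursion
shortfall: full at the primary action field, half at secondary fields, 20 %
elsewhere, plus a resting shift opposite the muscle's action) serve as a
regression catalogue: each must yield its generating muscle.

Cover–uncover interpretation smooths the filtered recording over 0.25 s,
detects a sustained deflection inside the covered interval that resolves
after uncover (post-interval level below 80 % of the deflection), and maps
the refixation direction to the latent deviation: abduction of the sensed eye
→ esotropia, adduction → exotropia, downward → hypertropia, upward →
hypotropia; the covered fellow eye is the fixating eye. The default detection
threshold (0.0015 ΔR/R) sits below the smallest sustained deflection of
interest, a downward refixation capped at 4 % eyelid strain.

## Agreement statistics

ICC uses the two-way random-effects, absolute-agreement, single-measurement
form (ICC(A,1)) computed from the two-way ANOVA mean squares, with the
standard F-based 95 % confidence interval — the conventional model for
method-comparison studies; it is cross-checked against an independent
implementation in the tests. Bland–Altman reports the mean difference and
95 % limits of agreement at bias ± 1.96 SD, with approximate confidence
intervals on the bias and on each limit (n ≥ 5). The mountain plot folds the
empirical CDF of differences at 0.5 using Hazen plotting positions
(i − 0.5)/n, peaking at the median. Stratified tables repeat both analyses
per stratum with a pooled row; strata below the estimation minimum (n < 3)
are flagged, never silently dropped. Whether repeated positions within a
patient may be pooled as independent observations is the caller's decision;
the functions compute on whatever pairing they are given.

## Problem sizes and numerical choices

The packaged benchmarks run on a 5,000-window, 10-subject cohort (50/50
split) for the 4-direction task, a 2,000-window cohort for the 8-direction
task, and a 10-subject calibration cohort with 80 events per subject; the
KNN-DTW baseline is evaluated on a 200-window training subsample with 4×
time decimation (DTW cost is quadratic in length, and the ≤1 Hz movement band
is untouched at 12.5 Hz). Sampling rate defaults to 50 Hz — the movement band
is ≤1 Hz, so this oversamples safely. Windows are float32; filters run in
float64. Ties in the max-pool backward pass route the gradient to the first
maximal element; KNN vote ties break toward the smaller summed distance.

## Known limitations

* The 10-channel expansion is one consistent reading of "channel difference
  and time difference"; it is isolated behind a single function so
  alternatives are drop-in.
* The regressor consumes window extrema rather than pooled network features;
  only its input width and parameter count are externally constrained.
* The Hess module models the 15° inner field on a tangent plane only — no
  curved tangent-scale lines, no 30° outer field, no torsion, and no
  red-green dissociation optics.
* Diagnosis thresholds (area ratio 0.85, shift 2°, underaction 2°) are
  clinically plausible defaults, exposed in configuration, not fitted values.
* The simulator's subject variability (gain multipliers, offsets) is far
  simpler than real inter-individual anatomy; synthetic benchmark numbers do
  not transfer to clinical accuracy claims.
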