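# Methods

`pulsetwin` implements a verification pipeline for photoplethysmogram (PPG)
pulse signals: filter-free preprocessing that condenses a short recording
into one fixed-length averaged pulse template, a weight-sharing twin 1-D
convolutional network that maps a pair of templates to a same-subject
probability, and the classical genuine/impostor evaluation stack
(ROC, AUC, FAR/FRR, EER). This note records the model, its assumptions,
the numerical choices, and what the synthetic benchmark does and does not
show.

## Preprocessing

The chain deliberately avoids bandpass or low-pass filtering, because the
high-frequency detail of a pulse waveform carries subject-specific
information that a filter would remove. Noise suppression comes instead
from averaging several cycles of the same heart beat.

1. **Detrending with normalisation.** With a forward moving mean
   `m_i = mean(x[i : i + w])` (window truncated at the end of the record),
   the signal becomes `d_i = (x_i − m_i) / m_i`. The division expresses
   amplitude in units relative to the local baseline, so records from
   different sensor gains become comparable, and the result has a
   near-zero baseline. The window `w` defaults to 75 samples (1.5 s at
   50 Hz, about two heart cycles): windows close to a single cycle beat
   against the heart period and visibly distort the detrended cycle shape,
   while two-cycle windows still track baseline drift of period ≥ 4 s.
   A zero local mean (impossible for raw PPG, which is strictly positive)
   is a hard error naming the offending index.

2. **Foot detection.** Cycle boundaries are the pulse feet: local minima
   of the detrended signal with value below zero. Scanning left to right,
   any candidate closer than `min_interval_s` (default 0.33 s, a 180 bpm
   ceiling) to the last accepted foot is discarded; this removes spurious
   dips that, in filtered pipelines, a smoother would have hidden. Feet in
   the final `w` samples of a record sit in the truncated-window region of
   the moving mean and can be biased late by a few samples; downstream
   averaging uses the first N cycles, so this only matters for the very
   last cycle of a record.

3. **Segmentation.** Cycle `j` is the half-open span `[foot_j, foot_{j+1})`;
   concatenating all cycles reproduces the signal between the first and
   last foot exactly. Fewer than two feet yield no cycles and the record
   is skipped with a per-record report, not a run failure.

4. **Quadratic-spline resampling.** Heart periods differ, so each cycle is
   resampled to `cycle_length` (default 50) points. On each knot interval
   the interpolant is

       S_i(t) = y_i + Z_i (t − x_i) + (Z_{i+1} − Z_i) / (2 (x_{i+1} − x_i)) (t − x_i)²

   with slopes given by `Z_1 = 0` and
   `Z_{i+1} = 2 (y_{i+1} − y_i)/(x_{i+1} − x_i) − Z_i`, the standard
   construction that makes the piecewise quadratic pass through every knot
   and be C¹ across them. The zero initial slope is the conventional
   closure; cycles start at a foot, where the waveform is near its
   flattest, so the choice is also physically reasonable. The evaluation
   grid spans the closed interval from first to last knot, endpoints
   included.

5. **Multicycle averaging.** The template is the pointwise mean of the
   first `N` resampled cycles (default `N = 5`, one template per record).
   For a fixed template plus independent zero-mean noise of variance σ²
   per cycle, the residual variance of the average is σ²/N — the
   quantitative content of the design, and a property the test suite
   checks for N = 1..5. Averaging also attenuates foot-detection jitter,
   which behaves like independent phase noise per cycle.

## Verifier

The network is a Siamese (twin) arrangement: one convolutional encoder,
used for both inputs — the two branches literally share one parameter set,
so sharing is structural rather than synchronised. The encoder has three
blocks of (1-D convolution, max pooling, batch normalization, ReLU) with
the same kernel size in every block; the flattened output is the
embedding. The similarity head takes the elementwise absolute difference
of the two embeddings through one hidden fully connected layer (64 units,
ReLU) and a final sigmoid unit, yielding a same-subject probability in
(0, 1). The absolute-difference merge makes the score exactly symmetric
under argument swap.

Architecture defaults (all configurable through `ModelConfig`): channels
16→32→64, kernel size 7, pool size 2, embedding 384, hidden 64. These are
implementation choices — on the synthetic benchmark kernel 7 separated
subjects consistently better than 5, and wider/deeper variants did not
help. Everything is implemented directly on NumPy with hand-written
forward and backward passes; with 50-sample inputs the model is small
enough that a deep-learning framework would add dependency weight without
speed, and the closed numeric core keeps runs bit-for-bit reproducible
from a single seed (the gradient code is verified against finite
differences in the test suite).

## Training

Pairs are drawn fresh every epoch, `len(pool)` of them: with probability
½ a genuine pair (uniform over all same-subject cycle pairs) and otherwise
an impostor pair, sampled in two stages — a uniform unordered subject pair,
then one cycle from each — so heavily represented subjects do not dominate
the impostor distribution. A cycle is never paired with itself. The loss
is binary cross entropy with predictions clamped to
[1e−7, 1 − 1e−7] against sigmoid saturation; the optimizer is Adam
(β₁ = 0.9, β₂ = 0.999) with learning rate 1e−4, batch size 32 and 500
epochs by default, no early stopping, no schedules, no validation-based
selection. Total pair exposures are exactly `pool × epochs` and the
trainer keeps a live counter plus a per-epoch mean-loss log.

## Evaluation

Every unordered pair of distinct test templates is scored (each template
is embedded once; the head then runs over all pair differences, which is
mathematically identical to scoring pairs one by one). For `s` subjects
with `m` templates each that is `s·C(m,2)` genuine and
`C(sm,2) − s·C(m,2)` impostor pairs. Metrics:

- **Accuracy at threshold** (default 0.5, the sigmoid midpoint): a score
  ≥ threshold accepts — stated explicitly because ties matter.
- **ROC/AUC**: swept over all distinct scores (scikit-learn, no dropped
  thresholds), AUC by trapezoidal integration; equals the probability a
  random genuine score exceeds a random impostor score, ties ½.
- **FAR/FRR/EER**: FAR(t) = fraction of impostor scores ≥ t, FRR(t) =
  fraction of genuine scores < t, swept over all distinct scores plus the
  endpoints 0 and 1. The EER is read at the FAR = FRR crossing with linear
  interpolation between the bracketing sweep points, which makes it
  deterministic and independent of sweep resolution.
- **Histogram**: both score distributions over 50 equal bins on [0, 1].

## Synthetic data

The generator exists so the whole pipeline can be exercised and its
claims tested without any external recordings. Each subject owns a beat
template: a positive baseline plus two Gaussian bumps — an asymmetric
systolic bump (upstroke steeper than decay, per-subject skew) and a
diastolic bump standing in for the dicrotic-notch region. The draw is
parameterised by systolic amplitude/position/width/skew, the
systolic-to-diastolic gap, the diastolic/systolic amplitude ratio, the
baseline level and the heart period; a floor on the diastolic width
(0.42 × gap) keeps the notch a shoulder above the local mean for every
admissible subject, as in real wrist PPG, so detrending never turns it
into a false foot. A `separability` knob in [0, 1] scales all parameter
windows: 0 gives every subject the population template, 1 the widest
spread; 0.6 is the "moderate" setting used in the scaled benchmark.

Records concatenate beats with per-beat period jitter (sd 0.02 s) and
amplitude jitter (5%), then add sinusoidal baseline drift (amplitude 0.15,
period 5 s) and white noise (sd 0.02, about 2% of the systolic amplitude).
The defaults emulate short low-noise wearable recordings — 6 s at 50 Hz,
resting heart rates of 75–94 bpm — the regime in which pulse-shape
biometrics is reported to work well; the noise terms are strong enough
that single-cycle templates are visibly degraded and multicycle averaging
has something to repair. Ground-truth foot positions (clean-signal minima)
are written to a sidecar file for the test oracles only; the pipeline
never reads them.

What the generator does **not** model: sensor transfer functions,
ambient-light interference, motion-artifact spectra, arrhythmia,
respiratory modulation, or any within-subject drift of beat morphology
over time. Passing the synthetic benchmark therefore shows that the
pipeline recovers subject identity from stable beat shape under additive
noise and timing jitter — not that it would survive ambulatory recording
conditions.

## Scaled benchmark

The end-to-end experiment uses 10 subjects × (40 train + 20 test) records,
separability 0.6, default noise, and a reduced training schedule of
150 epochs at learning rate 1e−3 (the default 500 × 1e−4 schedule is
matched to a ~1400-cycle pool; at our 400-cycle pool it yields ~11× fewer
optimizer updates, so the step size compensates). One run trains in
roughly half a minute on a single CPU. Across seeds the five-cycle model
reaches AUC ≈ 0.87–0.95 (three-seed mean ≥ 0.9) and beats the
single-cycle model in direction consistently; the equal error rate
improves accordingly. The suite asserts the three-seed mean and the
2-of-3 direction of effect rather than single-seed point values, because
with 10 random subjects the dataset draw itself is a visible source of
variance.

## Numerical notes and edge cases

- All randomness flows from one master seed through named substreams
  (data generation, pair sampling, weight initialisation, evaluation
  shuffles), so changing how one stage consumes randomness never perturbs
  another, and identical configurations reproduce score lists bit for bit.
- Sigmoid outputs are clamped to the open interval (0, 1) at 1e−12 so the
  similarity contract holds even for saturated logits.
- Records too short or too noisy to supply N cycles are skipped and
  reported per record; a manifest split with fewer than two subjects is a
  hard error.
- Batch normalization uses batch statistics during training (both twin
  branches pass through one concatenated batch, so they see identical
  statistics) and running statistics in evaluation, which keeps scoring
  deterministic and order-stable.
- `moving_mean` windows truncate at the record end rather than padding;
  the last `window_size` samples of a record are therefore systematically
  less trustworthy, a documented boundary effect.

## Known limitations

- The quadratic spline with `Z_1 = 0` can overshoot on steep cycles
  (quadratic splines have no local monotonicity control); cubic
  alternatives were out of scope by design.
- One template per record is produced from its first N cycles; long
  records are not sliced into multiple templates.
- The verifier is trained per dataset; no cross-dataset transfer or
  enrolment-update mechanics are provided.
- EER on small galleries is quantised by the discrete score sweep; the
  linear interpolation makes it stable but cannot add resolution that the
  pair counts do not contain.
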