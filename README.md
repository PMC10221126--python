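# pulsetwin

Biometric verification from photoplethysmogram (PPG) pulse shape.

A PPG sensor — the green light on the back of any smartwatch — records a
quasi-periodic pulse waveform whose fine morphology differs from person to
person. `pulsetwin` turns a few seconds of such a recording into a
fixed-length pulse template and decides whether two templates belong to
the same person, which enables passive, continuous authentication on
devices where typing a password is impractical.

The pipeline has three stages:

1. **Filter-free preprocessing.** The raw signal is detrended and
   normalised with a forward moving mean, `d_i = (x_i − m_i)/m_i`; pulse
   feet (sub-zero local minima, gated by a minimum beat interval) split it
   into single cycles; each cycle is resampled to 50 points with a
   quadratic spline; and the first *N* cycles are averaged pointwise,

       X = (1/N) Σ_{k=1..N} x_k ,

   which suppresses uncorrelated noise by 1/N in variance while leaving
   the subject-specific high-frequency detail — the reason no bandpass or
   low-pass filter is used anywhere.

2. **Twin-network similarity.** A Siamese 1-D CNN (three blocks of
   convolution, max pooling, batch normalization, ReLU; one shared
   parameter set for both branches) embeds each template; the elementwise
   absolute difference of the two embeddings passes through a small fully
   connected head ending in a sigmoid, giving P(same subject) ∈ (0, 1),
   exactly symmetric in its arguments. Training draws genuine and
   impostor pairs with probability ½ each and minimises binary cross
   entropy with Adam. The network is implemented directly on NumPy with
   hand-written backpropagation — small, dependency-light, and
   bit-reproducible from one seed.

3. **Genuine/impostor evaluation.** Every unordered pair of test templates
   is scored (for 35 subjects × 20 records: 6650 genuine, 238,000
   impostor, 244,650 pairs) and summarised as accuracy at a threshold,
   the ROC curve and AUC, FAR/FRR curves, the interpolated equal error
   rate (EER), and the two-class score histogram.

A built-in multi-subject synthetic PPG generator (per-subject beat
morphology, heart-rate and amplitude jitter, baseline drift, white noise,
ground-truth beat onsets for testing) makes the whole pipeline runnable
and testable with no external data.

## Worked example

Simulate a 10-subject dataset, then run the full pipeline (preprocess →
train → evaluate) with five-cycle averaging:

```sh
pulsetwin simulate --out demo --subjects 10 --train-records 40 \
    --test-records 20 --separability 0.6 --seed 42
pulsetwin run --manifest demo/manifest.tsv --n-cycles 5 \
    --epochs 150 --learning-rate 1e-3 --seed 42 --out demo_run
```

The second command prints:

```
n_genuine: 1900
n_impostor: 18000
n_total: 19900
threshold: 0.5
accuracy_at_threshold: 0.896030
auc: 0.925052
eer: 0.143684
eer_threshold: 0.189953
```

Reading: the 200 test templates (10 subjects × 20 records) form 19,900
pairs; the trained verifier ranks a random genuine pair above a random
impostor pair with probability 0.925 (AUC), and at the operating point
where false accepts and false rejects balance, both error rates are
≈ 14% (EER). `demo_run/` holds the score tables (`roc.tsv`,
`far_frr.tsv`, `histogram.tsv`), the per-epoch loss log, the model
checkpoint and the config — enough to regenerate every standard
verification plot. Rerunning the single-cycle baseline (`--n-cycles 1`)
on the same data and seed prints `auc: 0.898825`: the five-cycle average
is what buys the extra margin, and the gap widens with noisier data.

The same flow is available as a library:

```python
import pulsetwin as pt

manifest = pt.generate_dataset("demo", 10, 40, 20, separability=0.6, seed=42)
config = pt.RunConfig(n_cycles=5, epochs=150, learning_rate=1e-3, random_seed=42)
report = pt.run_pipeline(config, manifest)
print(report.summary_text())
```

`pulsetwin sweep --manifest demo/manifest.tsv --n-values 1,2,3,4,5 ...`
tabulates accuracy/AUC/EER as the number of averaged cycles grows.

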