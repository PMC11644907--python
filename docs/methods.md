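# Methods

This document records the mathematical models, the synthetic-data
assumptions, the default parameters and the numerical choices behind the
package, including known limits of the approach.

## 1. Error model

### Measurement

For a recording window, each modality is reduced to a scalar AC-coupled RMS:

- `eeg_avg`: RMS of the per-sample mean of the 8 EEG channels, after
  removing the window mean (µV);
- `accel_x/y/z`: RMS of each accelerometer axis after removing the window
  mean (g). AC-coupling removes the gravity DC offset from the z axis.

The *measured error* of a motion condition is the difference of these RMS
values between the motion recording and the stationary reference recording,
averaged over epochs.

### Per-factor law

For a factor `f` (surface friction µ, subject weight W, wheelchair weight
U) with reference level `x_1` and level `x_n`, the model is

```
E_n = ratio_n · Wf · E_1 + Cf,     ratio_n = x_1 / x_n
```

- `Wf` (weight factor) is fitted per non-reference level as
  `E_n / (ratio_n · E_1)` and averaged over levels (arithmetic mean).
- `Cf` (correction factor) is the mean residual `measured − predicted`
  over designated hold-out conditions (defaults: the two highest surface
  levels s4/s5, subject levels W4/W5, and the wheelchair levels U2/U3 —
  for the wheelchair factor only two non-reference levels exist, so fit
  and hold-out sets coincide).
- A zero reference error `E_1 = 0` is a calibration error: the
  multiplicative law cannot be normalized.

### Composition

- Accelerometer axes combine Euclidean-ly:
  `E = sqrt(Ex² + Ey² + Ez²)` per factor.
- The overall accelerometer error is the arithmetic mean of its three
  factor errors, `Ea = (Ea_s + Ea_p + Ea_w) / 3`.
- The total EEG-scale error is the arithmetic mean of the three EEG factor
  errors and the accelerometer error normalized to EEG scale:
  `E = (Es + Ep + Ew + Ea_norm) / 4`, with
  `Ea_norm = Ea · (E1_eeg / E1_accel)` using the Euclidean reference
  accelerometer error as the scale anchor.

### Correction

`apply_correction(avg, e_total)` rescales the averaged epoch so its
AC-coupled RMS drops by exactly `e_total` (floored at zero; a non-positive
error is the identity). It is a smooth amplitude rescale: waveform shape
(and hence all scale-invariant features) is preserved exactly.

### A structural limit of the averaged prediction

Because the total error averages the three factor terms, a condition set
that varies a single factor is *under-tracked*: only one of the averaged
terms follows the condition, so the predicted error moves with slope ≈ 1/3
of the true artifact change (multi-factor condition sets are under-tracked
more, since the truth composes multiplicatively while the model averages).
The correction therefore removes the condition-*mean* artifact amplitude
well but compresses only part of the condition-dependent *spread*. On
heavily contaminated data the net classification effect of the correction
is consequently small — the full-scale paired experiment in the acceptance
suite measures it directly (it came out marginally positive: mean accuracy
delta +0.0026 over three paired seeds at 640 epochs, with two seeds tied
and one improved). On artifact-free data the correction is, by
construction, near the identity (measured agreement: 0.000 accuracy gap).

## 2. Synthetic generator

Each recording is generated from a cue schedule (default: interleaved
RELAX/LEFT/RIGHT with a RELAX epoch before each motor-imagery epoch):

- **Background EEG**: per-channel Gaussian noise band-limited to 1–40 Hz,
  RMS `noise_rms` (default 10 µV). Incoherent across channels, so channel
  averaging attenuates it by ≈ √8.
- **Class signatures**: cue-locked sinusoidal bursts with random phase —
  LEFT: 12 Hz, 15 µV on C4 (and 0.4× on C3); RIGHT: 20 Hz on C3 (0.4× on
  C4); RELAX: none. The lateralized amplitudes are asymmetric so the
  signature survives channel averaging.
- **Motion artifact**: a common-mode, band-limited (0.5–10 Hz) component,
  mean-removed and normalized to an exact per-epoch RMS target. The
  reference recording carries RMS = `artifact_base_rms_eeg` (default
  20 µV); a motion condition carries `base · (1 + p)` where
  `p = Π_f ratio_f · Wf_true(f)` is the product of per-factor multipliers
  (1 at reference levels). The measured error is then exactly `base · p`.
- **Gain instability**: motion conditions multiply the clean EEG by
  `1 + gain_instability · p` (default slope 0.3), modelling
  electrode-contact modulation during vibration; it is 1 for reference
  recordings and when the artifact amplitude is zero.
- **Accelerometer**: vibration with the same multiplicative law in g,
  sensor noise, and a +1 g gravity offset on z.

Exact per-epoch RMS normalization (rather than normalization in
expectation) is what makes zero-noise calibration recovery exact to 1e-6
rather than statistical.

**Realism and limits.** The generator captures amplitude structure
(condition-dependent common-mode artifact, lateralized rhythms, band-limited
background), not physiology: no 1/f spectrum, no ocular/EMG artifacts, no
head-motion biomechanics, and the artifact is perfectly common-mode, which
is the idealized worst case for channel averaging. Friction coefficients
are free config inputs with plausible defaults (0.45–0.85); subject weights
default to 73.9–85 kg; wheelchair weights to 80/90/25 kg.

## 3. Features

14 features per series, computed on the averaged channel of 8 half-
overlapping sub-windows (window length `int(n / 4.5)`, e.g. 277 of 1250
samples), yielding an 8 × 14 grid per epoch:

- **Hjorth**: mobility `sqrt(var(Δx)/var(x))` and complexity, via first
  differences — for a sampled sinusoid of frequency f, mobility is exactly
  `2·sin(πf/fs)`; for white noise it converges to √2.
- **Moments**: mean, max, unbiased variance (ddof = 1), coefficient of
  variation `std/|mean|` (∞ sentinel for a zero mean), biased skewness and
  excess kurtosis.
- **Wavelet**: db4, level 4, *periodization* mode — orthogonal and
  energy-exact when the length is divisible by 2⁴ (at other lengths the
  internal padding perturbs Parseval slightly, ≤ ~1%). Detail energy is the
  sum of squared detail coefficients; detail entropy is the Shannon entropy
  (natural log) of per-level relative detail energies, bounded by ln 4.
- **Band powers**: maximum of the unwindowed periodogram
  `|rfft(x − mean)|²/n` within delta 0.5–4, theta 4–8, alpha 8–13 and beta
  13–30 Hz (half-open bands, beta closed at 30). Requires fs ≥ 60 and at
  least one bin per band.

Feature grids are standardized per feature across the training set before
classification.

## 4. Classifier

The layer-modified CNN (LM-CNN): Conv 3×3×32 (same, tanh) → BatchNorm →
Conv 3×3×64 → BatchNorm → MaxPool 2×2 → Dropout 0.5 → Flatten → Dense 100
(ReLU) → Dense 3 (softmax); Adam, lr 0.001. Baselines CNN2/CNN3/CNN4 are
reduced variants. The whole stack (forward, backward, Adam, dropout,
shuffling) is written in numpy against a single seeded generator, so
training is bit-reproducible and single-threaded by construction. A
non-finite loss raises a `DivergenceError`; model capacity vs input size is
validated at build time.

Metrics are accuracy, macro precision/recall/F1 (zero-division → 0) and
the confusion matrix, validated in the tests against scikit-learn as an
independent oracle. `grid_search_cv` performs stratified k-fold search over
batch size and epoch count.

## 5. Pipeline

`run_pipeline(recordings, use_empirical_model, cfg, seed, params=None)`
segments cue-locked epochs (reference recordings are excluded from the
classification pool), optionally calibrates (or reuses `params`) and
corrects each epoch, extracts feature grids, makes a stratified train/test
split, trains the configured model and returns the classifier, metrics and
a JSON-ready report fragment. `run_validation_case` runs cases a–d:
per-surface without correction (a), per-wheelchair-weight without (b), and
the corrected counterparts (c, d), calibrating once on the full input.

## 6. Numerical choices

- All RNG flows from `numpy.random.SeedSequence` spawning; no global state.
- Channel weights are renormalized so their mean is exactly 1 in the last
  bit, making the reshape round trip exact rather than approximate.
- RMS quantities are AC-coupled (window mean removed) everywhere, so DC
  offsets (amplifier drift, gravity) never leak into error estimates.
- Wavelet decomposition uses periodization mode for (near-)orthogonality;
  the decomposition level is capped by `pywt.dwt_max_level` for short
  windows.
- Stratified splits require at least one test sample per class; datasets in
  the tests are sized accordingly.
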