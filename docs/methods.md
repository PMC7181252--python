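# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind fogkit, and what its tests do and do not establish.

## Signal model and preprocessing

Input recordings are triaxial waist acceleration (units g, axes x/y/z) with
per-sample binary FOG labels, nominally sampled at 200 Hz. Analysis happens
at 40 Hz: all frequency content relevant to gait (0.5–3 Hz) and FOG
trembling (3–8 Hz, dominant 6–8 Hz) lies below 20 Hz, so 40 Hz suffices and
keeps window arithmetic simple. Resampling uses polyphase anti-aliased
decimation (`scipy.signal.resample_poly`); 200→40 Hz is an exact 1:5
decimation and the anti-aliasing filter prevents higher-frequency energy
from folding into the freeze band. Labels are resampled by
nearest-neighbour on the output time grid.

Band-limiting is a cascade of a 2nd-order 15 Hz low-pass (sensor noise) and
a 3rd-order 0.2 Hz high-pass (gravity and orientation drift), both digital
Butterworth filters applied **causally in a single forward pass**. Zero-phase
(forward–backward) filtering would look better offline but is acausal, and
the intended downstream use of a FOG detector is low-latency cueing. Filter
state is reset per recording; the start-up transient is kept rather than
trimmed (recordings are minutes long, windows near the edge are a negligible
fraction, and trimming would complicate sample-index bookkeeping).

Windows are 128 samples (3.2 s) with configurable overlap (0 / 50% / 75%);
indices are 0-based and windows are half-open `[start, start+128)`. The
label rule is deliberately asymmetric: FOG requires a strict majority
(> 64 samples), non-FOG requires purity (0 FOG samples), everything else is
discarded but counted, so the class balance of the windowed data can be
audited against the raw 10.5% sample imbalance.

## Feature representations

**Mazilu statistics (21).** Per axis: mean, standard deviation, variance,
spectral entropy, energy, freeze index, total band power. The published
description of this feature set lists eight names for seven features per
axis; we read "frequency, entropy" as a single feature — the Shannon
entropy (bits) of the normalised 64-bin power spectrum — and the "sum of
freeze index and locomotion band" as the total band power P(0.5–8 Hz),
matching the classic standing-detection guard band. Energy is the sum of
squared samples (not the mean square). Degenerate conventions: an all-zero
window has entropy 0 and freeze index 0; the freeze index is forced to 0
whenever locomotion-band power falls below 1e-12, because standing windows
otherwise produce unbounded ratios that carry no gait information.

**Inertial MFCCs (36).** Per axis: the 64-bin power spectrum is pooled by
20 triangular filters spaced on the mel scale over 0–20 Hz (the standard
speech warp, compressed onto the accelerometer's band, which concentrates
resolution at low frequencies where gait lives), log-compressed with a
1e-10 floor, and decorrelated by an orthonormal type-II DCT; coefficients
c0–c11 are kept.

**FFT spectra (192 / 384 / 576 / 768).** The 64 one-sided magnitude bins of
a 128-point FFT per axis; bin k sits at k·40/128 Hz. No taper is applied —
the signal is already band-limited and the representation feeds learned
models rather than a leakage-sensitive estimator; magnitudes (not log) are
stored. Band power sums squared magnitudes over bins whose centre frequency
lies in the half-open interval [f_lo, f_hi), so 3 Hz belongs to the freeze
band. Contextual stacking pairs window i with windows i−k…i−1 of the same
recording, oldest first; the first k windows of each recording are dropped,
and stacks never span recordings or subjects.

## Detectors

All detectors expose one contract: a scalar score per window, higher = more
FOG-like, which keeps the evaluation harness model-agnostic.

**Denoising autoencoder (novelty).** Dense layers 192–192–80–40 (tanh),
bottleneck 20 (ReLU), decoder 40–80–192; trained only on non-FOG spectra
scaled to [0, 1] by the training-set maximum, with Gaussian noise
(sd = 0.2, clipped back to [0, 1]) corrupting inputs while clean inputs
remain the target. Loss is binary cross-entropy with RMSprop; the score is
per-row reconstruction RMSE. The published description is ambiguous about
the output activation (tanh is named where BCE on [0, 1] data needs a
sigmoid); we default to sigmoid for consistency with the loss and keep tanh
available, in which case the loss falls back to MSE. Default regime: up to
250 epochs, batch 512, early stopping after 20 stagnant epochs.

**CNN (supervised).** Input (64, 3): two 1-D conv layers (32 filters,
kernel 8, ReLU), each followed by max-pool 2; dense 128 (dropout 0.5),
dense 32 (dropout 0.3), sigmoid output. Adam, BCE, 150 epochs, batch 512.

**CNN-LSTM (supervised, contextual).** Input (k+1, 64, 3): a shared conv
stack (128 then 64 filters, kernel 4, pool 2 each, flatten to 832) applied
identically to every time step via a time-distributed wrapper, a 64-cell
LSTM, dense 80 and 40 (ReLU), sigmoid output. Adam, BCE, 150 epochs,
batch 1024.

**Shallow baselines.** SVC (RBF, γ = 0.3, C = 1), AdaBoost (100
estimators), random forest (100 trees), one-class SVM (linear kernel,
fitted on non-FOG rows; score is the negated decision function). These go
through scikit-learn.

Deep-model conventions: learning rate 1e-4, element-wise gradient clipping
at 1, early stopping on training loss with patience 20, Glorot-uniform
initialisation, forget-gate bias 1, valid (no) conv padding, pooling
truncates odd lengths, dropout active only in training. Max normalisation
(0–1 by training max) is applied to all deep models, not just the
autoencoder, for comparability; normalisation statistics come from the
training fold only and are stored on the detector. No class rebalancing or
weighting is applied. All randomness flows from one seed, so identical
configurations reproduce identical scores on a given platform.

The layers, optimizers (Adam, RMSprop with clipvalue semantics) and the
training loop are implemented in `fogkit.nn` directly on NumPy with manual
backpropagation; gradient correctness is established by central-difference
checks in the test suite for every layer type, in float64.

## Evaluation

**Metrics.** ROC AUC by trapezoidal integration; the operating point is the
ROC vertex minimising |sensitivity − specificity|, ties resolved toward the
lower threshold; EER is the mean of the two error rates there (equal to
1 − sensitivity at an exact crossing); GM = √(sensitivity·specificity).
Folds with a single class raise an undefined-metric error rather than
returning a silent default.

**LOSO.** One fold per held-out subject per repeat; repeats (default 6)
differ only in training seed and shuffling, with the data fixed. The
harness hard-asserts that the held-out subject contributes no training row.
Cohort aggregates are arithmetic means over all folds and repeats
(mean-of-folds, not pooled-scores AUC — matching how per-patient tables are
usually averaged; with per-subject score scales pooling would conflate
calibration with discrimination).

**R10fold.** Stratified random folds within one subject (each fold receives
both classes whenever the subject has ≥10 windows per class; round-robin
dealing otherwise degrades gracefully). Random folds are the point: with
75% overlap, adjacent windows share 96 of 128 samples, and the harness
reports how many test windows intersect a training window — the mechanism
behind optimistic personalised results. `grouped=True` switches to
contiguous blocks for a low-leakage comparison but is off by default.

## Synthetic cohort

The generator's defaults encode the study conditions the pipeline assumes:
21 subjects, two 20-minute recordings each, 200 Hz, 10.5% FOG samples.
Per-subject parameters are drawn once per cohort: gait fundamental
U(0.9, 1.4) Hz (so the second harmonic stays inside the locomotion band and
the weak third harmonic contributes little freeze-band energy), gait
amplitude U(0.2, 0.4) g, tremble frequency U(6, 8) Hz, tremble amplitude =
gait amplitude × contrast × U(0.8, 1.2) with contrast 1 by default, sensor
noise sd U(0.02, 0.05) g, mean episode length U(5, 9) s. A walk/stand
semi-Markov schedule (gamma-distributed segments, means 25 s and 6 s)
carries a shared motion component distributed to the three axes by
subject-specific gains, plus independent noise and a constant 1 g gravity
offset on the vertical axis (so the high-pass stage is genuinely
exercised). FOG episodes are placed only inside walking segments (freezing
manifests when gait is attempted), separated by at least 0.5 s, with total
episode time budgeted to the target fraction (last episode truncated), so
the realised class balance tracks 10.5% closely; the cohort constructor
fails loudly if the realised fraction strays more than 2 points.

What the simulator does **not** emulate: realistic gait biomechanics,
ON/OFF medication states, festination or pre-freeze gait degradation,
sensor saturation and re-orientation artefacts, or the heavy-tailed
episode statistics of real patients. Consequently, passing the synthetic
trend tests shows the pipeline is wired correctly and sensitive to the
spectral signature of FOG — it does not predict clinical performance. The
synthetic task is much easier than real FOG detection: supervised deep
models reach ceiling AUC at moderate difficulty, so between-model margins
on synthetic data are compressed relative to clinical data. The
`amplitude_contrast` knob exists to re-introduce difficulty: downstream
LOSO AUC decreases monotonically as the contrast shrinks.

## Scaled-down experiment sizes

The packaged experiment presets and the heavier tests run reduced problem
sizes, chosen as this package's own defaults for a single-CPU workflow: the
contextual-trend experiment uses 6 subjects × 10 minutes, non-overlapping
windows, and trains the CNN-LSTM for 20 epochs with batch 128 and learning
rate 1e-3 (fewer epochs warrant larger steps than the full-scale 1e-4
regime); the novelty experiment trains the autoencoder for up to 60 epochs
at learning rate 1e-3. These settings change absolute metric values, not
the qualitative orderings the tests assert.

## Known limitations

* The NumPy training loop is single-threaded and eager; it is sized for
  method verification, not for full-scale 21-subject × 6-repeat LOSO sweeps
  with the published epoch counts.
* Early stopping monitors training loss (no validation split is carved out
  of the training fold), which matches the published regime but offers no
  overfitting guard beyond the epoch cap.
* The equal-error operating point is computed per fold; with very few test
  windows of one class the discrete ROC makes sensitivity ≈ specificity
  only up to 1/min(n₁, n₀).
* Only the accelerometer is modelled; gyroscope/magnetometer channels and
  on-device streaming are out of scope.
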