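# Methods

## Scope

`tfppnet` implements a seizure-detection pipeline for multichannel scalp
EEG: connectivity-based feature construction (PCC, PLV, their Hadamard
fusion, and the time–frequency PP tensor), a hybrid CNN/Transformer
classifier with selective-kernel attention, a cross-validated training and
evaluation protocol, and a seeded synthetic-EEG generator that makes all of
it testable end to end. This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic EEG generator

Each channel is a variance-normalized mixture

    s_c(t) = sqrt(k) · d(t; φ_c) + sqrt(1 − k) · σ · n_c(t)

with `n_c` independent **pink (1/f) noise** — resting EEG spectra are
1/f-like, and white noise would make per-band behaviour unrealistic — and
`d` a common drive. Outside seizures the drive is a shared pink-noise
process and `k` is the interictal coupling (default **0.1**, not 0, so
interictal networks are weak and sparse rather than exactly empty). Inside
annotated seizure intervals the drive is a sinusoid at `drive_freq`
(default **3 Hz**, mimicking spike-wave rhythmicity) with **20 %**
sinusoidal amplitude modulation at 0.5 Hz and a fixed per-channel phase
offset drawn with std `phase_jitter` (default **0.1 rad**); `k` is the
ictal coupling (default **0.8**). Output units are arbitrary
(microvolt-like); no calibration is claimed. Identical config + seed gives
bit-identical signals.

What the generator emulates is exactly the contrast the method exploits:
globally elevated amplitude correlation and phase synchrony during
seizures. What it does **not** emulate: physiological seizure morphology
(spike-wave shape, evolution, focal onset and spread), artifacts (EMG, eye
blink, electrode pop), inter-subject variability, or non-stationary
background. Passing tests therefore demonstrate that the pipeline detects
coupling contrasts of the stated size — not clinical-grade performance on
real recordings.

## Connectivity estimation

* **PCC** is the sample Pearson correlation of the two amplitude series.
  Zero-variance channels raise an error naming the channel rather than
  emitting NaN networks. The matrix is symmetrized (`(R + Rᵀ)/2`) and
  clipped to [−1, 1] to remove floating-point residue.
* **PLV** takes instantaneous phases from the Hilbert analytic signal and
  averages the unit phasors of the pairwise phase differences. Because the
  analytic signal is unreliable at window edges, **10 % of samples at each
  end are discarded** before averaging (configurable `edge_trim`; the
  definition-equivalence tests use `edge_trim=0`). A minimum of 8 samples
  is required; all-zero channels are rejected (phase undefined).
* **Fusion**: PP = |PCC| ∘ PLV. The absolute value keeps anti-correlated
  pairs from cancelling; the entrywise product assigns weight only where
  amplitude and phase synchrony agree, giving PP ≤ min(|PCC|, PLV)
  entrywise with values in [0, 1].
* **Band-limited connectivity** is computed on time-domain reconstructions:
  per channel, an STFT (Hann taper, 1-s windows, 50 % overlap), zeroing of
  bins outside [lo, hi), and inverse STFT. This keeps the PCC/PLV
  definitions unchanged per band, as opposed to defining connectivity on
  STFT coefficients directly, which would need a separate estimator. Bands
  default to the clinical rhythms δ(1–4), θ(4–8), α(8–13), β(13–30),
  γ(30–50) Hz and are fully configurable.
* **TFPP tensor**: for each 4-s segment, PP matrices of `n_subwindows`
  (default **2**) equal broadband time sub-windows, then one whole-segment
  PP per band in configuration order. The slice ordering is recorded
  explicitly and enforced to be identical across a dataset. Sub-windows
  shorter than 64 samples are rejected as too short for stable estimation.
  For the single-network ablation inputs the same stack is built from
  |PCC| or PLV matrices alone.

## Preprocessing

Band-pass 1–50 Hz (4th-order Butterworth, zero-phase `sosfiltfilt`; the
filter family is a package choice). Sliding 4-s windows from time 0 with a
default stride of 4 s; a window is labeled ictal when its overlap with any
annotated seizure interval is at least half the window (configurable). An
optional denser grid (`ictal_stride_s`) adds extra *ictal* windows only,
densifying the scarce class. Class balance is restored by duplicating
minority windows at random (no synthetic interpolation — duplication never
fabricates signal values), and only ever inside a training split.
Annotations are half-open `[start, end)` intervals in seconds, stored as a
plain-text sidecar next to each EDF. EDF reading uses `mne`; EDF writing is
a minimal 16-bit EDF+ writer (1-s records, per-channel physical scaling),
round-trip-tested against the `mne` reader.

## SeizureTransNet

The architecture follows EEGNet conventions for the convolutional front
end and a pre-norm Transformer for context:

* temporal convolution (kernel **64**, **8** filters, no bias), depthwise
  spatial convolution collapsing the electrode axis (depth multiplier
  **2**), then two depthwise-separable blocks (depthwise kernel **15** +
  pointwise 1×1) — separable blocks use strictly fewer parameters than
  dense convolutions of the same receptive field. Average pooling
  (**4, 8**) and dropout (**0.25**) sit between stages; normalization is
  per-(sample, feature-map) over time, which has no running statistics and
  keeps seeded runs bit-reproducible. The pooled maps give
  `T/(p₁·p₂)` tokens.
* the connectivity stream projects each flattened C×C slice to one
  `d_model` token. The dual-stream token sequence reproduces all four
  ablation inputs (eeg, eeg+pcc, eeg+plv, eeg+tfpp) with one architecture.
* encoder (**2** blocks, `d_model` **64**, **4** heads): pre-norm
  multi-head self-attention with residual, then a pre-norm SK-attention
  feed-forward with residual. SK attention runs depthwise convolutions with
  kernels **(3, 5)** along the token axis, pools their sum into a global
  descriptor, and produces per-branch, per-feature softmax weights — a
  convex combination of the branches. A learnable class token and learnable
  positional encodings (matching the learnable token) are used.
* head: layer norm → linear → ELU → dropout (**0.5**) → linear to 2 scores.

All hyperparameters above are package defaults exposed in the config; they
are EEGNet-scale values chosen for small-data stability (pre-norm residual
blocks, bias-free convolutions followed by normalization).

The network runs on an in-package reverse-mode autodiff engine over numpy
(float32 end to end; FFT-based long temporal convolutions). Every
primitive's gradient is verified against central finite differences in the
test suite, and Adam follows the standard (β₁, β₂) = (0.9, 0.999),
lr 10⁻³ recipe.

## Training and evaluation protocol

Stratified k-fold cross-validation (default k = 10) at segment level;
fold averages are arithmetic means. Within each training split, a
stratified 10 % validation subset drives early stopping (patience 10
epochs, best-validation-loss parameters restored), and oversampling is
applied **after** splitting, to the training portion only — the opposite
order would leak duplicated ictal windows into test folds. Batch size 256
(capped at the training-set size). Metrics: Acc, Sen, Spe from confusion
counts; AUC by the rank (Mann–Whitney) formulation with ties counted ½,
which equals trapezoidal ROC integration and is cross-checked against an
independent implementation in the tests. Metrics whose denominator class is
absent are reported as undefined, never as 0.

Segment-level folds let temporally adjacent (and, with a dense ictal grid,
overlapping) windows of one seizure land in train and test, which inflates
metrics relative to event-level splitting; `kfold_split(groups=...)` offers
grouped folds for the conservative protocol. Neither mode is claimed to
match any external study's protocol.

## Problem sizes in the tests and acceptance script

The synthetic benchmark uses 200 segments per class (18 channels, 256 Hz,
4-s windows, coupling 0.8 vs 0.1), 2-fold cross-validation over three
seeds, and a reduced model (4 temporal filters, `d_model` 32, 1 encoder
layer, batch 64, ≤ 8 epochs) — sizes chosen so the full suite runs in
minutes on one CPU while still exercising every architectural component.
On this benchmark the fused eeg+tfpp input reaches held-out AUC ≥ 0.99 and
never falls below the raw-EEG ablation; the scripted run writes the exact
numbers it measures to JSON rather than this document quoting them.

## Known limitations

* The synthetic benchmark is far easier than clinical EEG; results on it
  bound nothing about real recordings (see generator limitations above).
* The EDF writer covers the subset of EDF+ the pipeline needs (uniform
  sampling rate, 16-bit, 1-s records); it is not a general EDF library.
* The numpy training engine is single-device and unoptimized for large
  models; it is sized for the segment lengths and model widths used here.
* No artifact handling: myogenic or electrode artifacts would corrupt both
  connectivity estimation and classification.
* `eeg+pcc` / `eeg+plv` modes reuse the TFPP slice layout with single-
  estimator matrices; whether per-band single-network stacks should instead
  skip fusion entirely is underdetermined, and this choice is exposed via
  the `kind` argument rather than hidden.
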