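# Methods

This note documents the models, numerical choices and limitations behind
`seqmotor`. Units are seconds, Hz and microvolts throughout; channel
order is montage order; epochs use the half-open window convention
`[tmin, tmax)` with time 0 at the first keystroke of a trial.

## Paradigm and synthetic data

Each trial consists of a 1 s ready cue, a task prompt (LL, RR, LR or RL),
a first keystroke ≈2 s after the prompt, a second keystroke 1.0 s later
(Gaussian jitter, σ = 50 ms, truncated at ±150 ms), and a 2 s rest. The
offline protocol is 10 blocks × 60 trials with each task exactly 15 times
per block in seed-determined order (600 trials, 150 per task); the online
protocol is 6 such blocks (360 trials) plus a 40-trial LL/RR block and a
40-trial LR/RL block (20 + 20 each, shuffled).

The generator renders this schedule into a continuous recording as the
sum of:

* **MRCP**: per keystroke, a linear negative ramp from 1.5 s before the
  press to a −8 µV peak at the press, returning to baseline along a
  half-cosine over 0.5 s. The spatial pattern is a Gaussian kernel
  (σ = 45 mm over scalp x/y coordinates) centered on the hand area
  contralateral to the moving finger (C4 for left, C3 for right), plus
  the ipsilateral kernel down-weighted by the contralateral ratio
  (default 2). For repeated sub-action tasks (LL, RR) the second
  keystroke's amplitude is scaled by 0.8, reflecting the weaker
  non-initial negativity of repeated movements.
* **Oscillations with ERD**: ongoing 10 Hz alpha (5 µV) and 20 Hz beta
  (2 µV) whose amplitude is multiplied by (1 − depth) inside a 1 s window
  centered on each keystroke, with the same contralateral spatial
  weighting (defaults: alpha depth 0.5, beta depth 0.3). Oscillation
  phase is locked to the first keystroke of each trial (per-channel
  deterministic offsets). This makes the zero-noise, zero-jitter class
  template exactly recoverable by trial averaging — a strong test hook —
  at the cost of realism: genuine induced activity is not phase-locked.
  Trial-averaged *power* estimates (the ERSP path) are unaffected by this
  choice.
* **Noise and artifacts**: per-channel 1/f-amplitude background noise
  (default 4 µV RMS, flat below 1 Hz), a common-mode 50 Hz sinusoid
  (2 µV) that CAR removes exactly, and optional frontal blink artifacts
  (Poisson process, 120 µV sin² bumps of 0.4 s projected through a
  frontal Gaussian kernel; off by default). The noise scale was fixed
  once so that the full pipeline decodes the four tasks well above
  chance; it is deliberately not an SNR sweep.

What the generator does **not** emulate: volume-conducted source
geometry, non-stationary rhythms, inter-subject variability, electrode
drift, EMG. Passing tests therefore demonstrate the correctness of the
pipeline's computations and its sensitivity to the planted structure —
not performance on real recordings.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical
recordings.

## Preprocessing

* "4th-order zero-phase Butterworth" is implemented as a 4th-order design
  applied forward–backward (`sosfiltfilt`), i.e. an effective 8th-order
  magnitude response; a "0–X Hz" band is a plain low-pass at X Hz.
* The notch is a second-order IIR design (Q = 30) applied forward–
  backward.
* Resampling is polyphase with the built-in anti-alias filter; event
  sample indices rescale with round-half-away-from-zero.
* The rejection rule drops a trial iff its key codes contradict the
  task's expected sequence, the keystrokes are separated by more than
  2 s, or it has other than two key events ("malformed").
* ICA artifact removal is automated (FastICA; components whose absolute
  correlation with an EOG reference exceed a threshold, default 0.8, are
  subtracted from the sensor data). Manual component review is out of
  scope, and the stage is optional and off by default. Only the removed
  components are subtracted, so removing nothing is exactly the identity.
  The pipeline order is notch → (optional ICA) → branch-specific
  filtering.

## MRCP and ERSP

The MRCP branch resamples to 16 Hz, low-passes at 3 Hz, applies CAR and
epochs [−2, 3) s (80 samples). No baseline correction is applied beyond
the low-pass and CAR. Grand averages are computed subjects-first where a
subject partition is given; the pointwise paired t-test operates on the
subject means, two-sided, with raw p < 0.05 shading by default (a
Bonferroni option exists but is off, matching common ERP practice of
reporting uncorrected pointwise tests). Zero-variance differences are
flagged degenerate with p = 1. Topographies snap requested times
(−150 ms, 850 ms) to the nearest 16 Hz grid point and report the snapped
time.

The ERSP branch resamples to 200 Hz, applies CAR, band-passes 4–30 Hz
and epochs wide enough for the [−1.5, 2.5] s grid plus half an STFT
window (256/200 s). Power is estimated with a 256-sample Hann window and
64-sample hop (frequency resolution 0.78125 Hz — forced by the window
length), averaged over trials **in power**, converted to dB
(10·log₁₀), linearly interpolated onto a 50 ms reporting grid, and
baseline-subtracted per frequency with the mean over [−1.5, −1] s. dB
units with power-domain trial averaging follow standard ERSP practice;
averaging dB values instead yields a different (rejected) estimator, and
a raw-power mode is available behind `db=False`. ERSP is consequently
invariant to global amplitude rescaling.

## Feature bank

Feature epochs cover [−0.5, 1.5) s at 200 Hz (400 samples), anchored to
the first keystroke only, so one window spans both keystrokes at ~1 s
spacing. (Per-keystroke overlapping epochs would be a defensible
alternative; single anchoring keeps one feature vector per trial.)

* **DCPM** (1–8 Hz branch). Per class, one-vs-rest discriminative
  spatial patterns: top-2 generalized eigenvectors of the between-class
  scatter (class mean vs rest mean) over the within-class trial scatter.
  The class template is the projected class mean. Per epoch and class,
  four similarities: the Pearson correlation of each projected dimension
  with the template, and the two canonical correlations (CCA) between
  the 2-D projected epoch and the 2-D template. 4 classes × 4 = 16
  features. The internal composition of the 16 is an assumption — the
  count is fixed but its decomposition is not uniquely determined by the
  method's published description; this construction is the minimal one
  consistent with 2 DSP dimensions, CCA alignment and 4 classes.
* **TRCA** (1–8 Hz branch). Per class, filters maximizing the summed
  inter-trial covariance over the average trial covariance (top 3
  eigenvectors); the feature is the Pearson correlation between the
  projected epoch and projected template with components concatenated —
  one per class, 4 features.
* **FBCSP** (theta 4–8, alpha 8–13, beta 13–30 Hz). Per band and class,
  one-vs-rest CSP: generalized eigenvectors of (class covariance,
  class + rest covariance), eigenvalues in (0, 1), top 3 filters; trial
  covariances are trace-normalized by default. Features are
  log(vᵢ / Σv) of the projected variances — scale invariant. 3 bands ×
  4 classes × 3 filters = 36. One-vs-rest (not pairwise) pairing is what
  makes the count 36.

All scatter/covariance matrices receive scalar convex shrinkage toward
tr(C)/n·I with fixed intensity 0.05 (60 channels × few trials per fold is
otherwise rank-deficient; a data-driven Ledoit–Wolf intensity would
require raw-sample access per matrix and adds little for these sizes).
Eigenvector signs are fixed by making the largest-magnitude coefficient
positive, so outputs are platform-deterministic. A singular matrix with
shrinkage disabled raises an error instructing the user to enable it.

## Decoding

Mutual information between each feature and the label uses equal-width
10-bin discretization over the feature's training range and the exact
plug-in estimator on the joint histogram, in bits (deterministic and
directly testable against the closed form; affine-invariant because the
bins rescale with the range). Ties rank by ascending feature index.
Constant features score 0.

Classification is a linear SVM (C = 1, one-vs-one with vote tie-break by
class index — the convention of the underlying library family).
Features are z-scored with fold-train statistics, since a C = 1 linear
SVM is scale-sensitive. Offline evaluation is stratified 10-fold CV with
seeded shuffling at trial level (block-level stratification would be an
alternative; trial-level is implemented and documented).
`crossvalidate_epochs` refits the entire spatial-filter bank inside each
fold so no test trial touches any fitting step; `crossvalidate` operates
on a precomputed feature matrix and keeps MI/scaler/SVM fold-hygienic.
The reported mean accuracy is the pooled confusion-matrix trace over the
total count. The offline "optimal" feature count is resolved by nested
CV over k ∈ {5, 10, …, 55, 56}; the online configuration fixes k = 10.

The online simulation fits the bank once on blocks 1–6 (all four
classes), then trains one binary MI + SVM pipeline per feedback pair
(LL-vs-RR for block 7, LR-vs-RL for block 8) on that pair's training
trials only, and emits one decision per test trial.

## Problem sizes

Defaults reproduce the study conditions: 60 channels at 1,000 Hz, 10 × 60
offline trials, 8-block online protocol. The test suite and the
acceptance script run the same protocols on a 23-channel
sensorimotor-focused montage at 250 Hz (all analysis bands lie well below
the 125 Hz Nyquist), which preserves every structural property while
keeping a full run to a couple of minutes; individual unit tests use a
12-channel montage and single blocks. These sizes are the package's
documented defaults for simulation-based verification.

## Known limitations

* The DCPM 16-feature decomposition and the MI estimator are explicit
  design choices where the method's description fixes only counts; other
  constructions could alter absolute accuracies.
* The synthetic LR/RL contrast relies mostly on temporal order of
  mirrored spatial patterns; their mutual confusability is higher than
  for LL/RR, and online LR-vs-RL accuracy varies more across seeds.
* Real-data performance claims cannot be validated here; the generator's
  amplitudes are plausible but not calibrated to any subject population.
* ICA unmixing quality on the synthetic 1/f + blink model is easier than
  on real EEG; the removed-component count on defaults is small, unlike
  the 5–10 components typically removed by manual review of real
  recordings.
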