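# seqmotor

EEG decoding of **sequential finger movements** for brain–computer
interfaces: a tested, reusable implementation of the full analysis chain
for a keystroke paradigm in which subjects press two keys about 1 s apart
with the left or right index finger, giving four tasks — LL, RR, LR, RL
(first letter = first keystroke).

The package is aimed at BCI/neural-engineering researchers who want to
study or extend sequence-based movement decoding without access to the
original recordings: a paradigm-faithful synthetic EEG generator stands in
for the amplifier, and every downstream stage operates identically on real
data loaded from EDF or delimited text.

## What it computes

* **Synthetic EEG** (`seqmotor.synth`): 60-channel 10-20 montage at
  1,000 Hz with 50 Hz line interference; per trial a cue, two keystrokes
  ≈1 s apart, a movement-related cortical potential (MRCP: negative ramp
  peaking at the key press) with contralateral dominance (left finger →
  C4 side, right → C3 side), alpha/beta event-related desynchronization
  (ERD) around each keystroke, 1/f background noise and optional blinks.
  The offline protocol is 10 blocks × 60 trials (15 per task per block);
  the online protocol is 6 such blocks plus two 40-trial feedback blocks
  (20 LL + 20 RR, then 20 LR + 20 RL).
* **Preprocessing** (`seqmotor.preprocess`): 50 Hz IIR notch, zero-phase
  Butterworth filters, polyphase resampling, common average reference
  (CAR), the behavioral rejection rule (wrong key codes or keystrokes
  separated by more than 2 s), and automated ICA ocular-artifact removal.
* **MRCP analysis** (`seqmotor.mrcp`): 16 Hz / 3 Hz low-pass / CAR /
  [−2, 3) s epochs around the first keystroke; grand averages
  (subjects-first), pointwise paired t-tests, −150 ms and 850 ms
  topographies.
* **ERSP analysis** (`seqmotor.ersp`): 200 Hz / CAR / 4–30 Hz; STFT with a
  256-sample Hann window; ERSP = ERSP_original − ERSP_baseline in dB with
  the baseline mean over [−1.5, −1] s; alpha-band (8–13 Hz) topographies
  for the two sub-action windows (−0.5–0.5 and 0.5–1.5 s).
* **Feature bank** (`seqmotor.spatial_features`): on [−0.5, 1.5) s epochs
  at 200 Hz, a 1–8 Hz branch feeds DCPM (discriminative spatial patterns +
  CCA template matching, 2 dimensions per class) and TRCA (inter-trial
  covariance maximization, 3 components per class); a theta/alpha/beta
  filter bank feeds one-vs-rest CSP (3 filters per band and class) —
  56 features per trial (16 DCPM + 4 TRCA + 36 FBCSP).
* **Decoding** (`seqmotor.decode`): mutual-information feature ranking
  (equal-width 10-bin histograms, bits), top-k selection (k = 10 online),
  linear SVM with C = 1, stratified 10-fold cross-validation with
  fold-wise refitting of the whole bank, nested-CV feature-count sweeps,
  and an online simulation that trains on blocks 1–6 and classifies the
  two feedback blocks.

## Worked example

```python
import seqmotor as sm

montage = sm.standard_montage(sm.MOTOR_CHANNELS)      # 23-channel subset
schedule = sm.make_protocol(n_blocks=2, trials_per_block=60, seed=42)
rec = sm.simulate_dataset(schedule, sm.SignalModelParams(), montage,
                          rate=250.0, seed=42)

# MRCP grand averages: contralateral negativity before the first keystroke
epochs = sm.mrcp_pipeline(rec)
ga = sm.grand_average(epochs)
c3, c4 = montage.index("C3"), montage.index("C4")
win = (ga.times >= -0.3) & (ga.times <= 0.0)
for task in sm.TASKS:
    print(f"{task}: C3 {ga.waveforms[task][c3, win].mean():6.2f} uV   "
          f"C4 {ga.waveforms[task][c4, win].mean():6.2f} uV")

# end-to-end four-class decoding (bank refitted inside each fold)
fe = sm.prepare_feature_epochs(rec)
report = sm.crossvalidate_epochs(fe, sm.DecoderConfig(seed=42))
print(f"four-class accuracy: {report.mean_accuracy:.2f}%")
```

prints

```
LL: C3  -0.68 uV   C4  -5.04 uV
RR: C3  -4.46 uV   C4   0.32 uV
LR: C3  -2.01 uV   C4  -4.40 uV
RL: C3  -4.71 uV   C4  -1.95 uV
four-class accuracy: 40.83%
```

Left-initial tasks (LL, LR) are more negative at C4 (right hemisphere),
right-initial tasks at C3 — the contralateral pattern the analysis is
built to detect. 120 trials already decode well above the 25% chance
level; the full 600-trial offline protocol reaches ≈73% under the default
noise model (see below).

A command-line interface mirrors the library
(`seqmotor simulate|preprocess|mrcp|ersp|features|classify|online-sim`),
reading a YAML configuration and writing EDF recordings, tab-delimited
tables and JSON reports.

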