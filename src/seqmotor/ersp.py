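"""Event-related spectral perturbation (ERSP) via short-time Fourier transform.

Pipeline: resample to 200 Hz -> common average reference -> 4-30 Hz
band-pass -> epochs wide enough to support the [-1.5, 2.5] s reporting
window plus half an STFT window of padding.  Power is estimated with a
256-sample Hann window (hop 64 samples), averaged over trials, converted to
decibels, interpolated onto a regular reporting grid, and
baseline-subtracted: ERSP = ERSP_original - ERSP_baseline, with the
baseline the per-frequency mean over [-1.5, -1.0] s.  Negative values are
event-related desynchronization (ERD), positive values synchronization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import TASKS, ChannelMontage, ContinuousRecording, EpochSet, \
    extract_epochs
from .preprocess import butterworth_filter, common_average_reference, resample


@dataclass
class ERSPMap:
    """Channels x frequencies x times baseline-subtracted perturbation (dB)."""

    values: np.ndarray          # channels x freqs x times, dB
    freqs: np.ndarray           # Hz
    times: np.ndarray           # s relative to the first keystroke
    baseline_window: tuple[float, float]
    original: np.ndarray        # pre-subtraction dB map
    baseline: np.ndarray        # channels x freqs per-frequency baseline mean
    montage: ChannelMontage


def ersp_pipeline(rec: ContinuousRecording, target_rate: float = 200.0,
                  band: tuple[float, float] = (4.0, 30.0),
                  trange: tuple[float, float] = (-1.5, 2.5),
                  window_len: int = 256) -> EpochSet:
    """Resample -> CAR -> band-pass -> wide epochs for the ERSP grid."""
    out = resample(rec, target_rate)
    out = common_average_reference(out)
    out = butterworth_filter(out, low=band[0], high=band[1], order=4,
                             zero_phase=True)
    half = window_len / (2.0 * target_rate)
    return extract_epochs(out, trange[0] - half, trange[1] + half)


def compute_ersp(epochs: EpochSet, window_len: int = 256, hop: int = 64,
                 baseline: tuple[float, float] = (-1.5, -1.0),
                 trange: tuple[float, float] = (-1.5, 2.5),
                 freq_band: tuple[float, float] = (4.0, 30.0),
                 grid_step: float = 0.05, db: bool = True,
                 task_order: tuple[str, ...] = TASKS) -> dict[str, ERSPMap]:
    """Per-task trial-averaged ERSP maps.

    Trial averaging happens on power before the dB conversion; set
    ``db=False`` for raw power ratios (baseline then divides instead of
    subtracting in log space).
    """
    if not (trange[0] <= baseline[0] < baseline[1] <= trange[1]):
        raise ValueError("baseline window must lie inside trange")
    rate = epochs.rate
    if epochs.n_samples < window_len:
        raise ValueError("epochs shorter than the STFT window")

    window = sps.get_window("hann", window_len)
    # frame times: spectrogram uses only full windows (no padding)
    freqs, frame_t, power = sps.spectrogram(
        epochs.data, fs=rate, window=window, noverlap=window_len - hop,
        axis=-1, mode="psd")
    frame_times = epochs.tmin + frame_t          # window-center times
    fsel = (freqs >= freq_band[0]) & (freqs <= freq_band[1])
    freqs = freqs[fsel]
    power = power[:, :, fsel, :]                 # trials x ch x f x frames

    grid = np.arange(trange[0], trange[1] + 1e-9, grid_step)
    out: dict[str, ERSPMap] = {}
    bsel_grid = (grid >= baseline[0]) & (grid <= baseline[1])
    for task in task_order:
        sel = epochs.labels == task
        if not sel.any():
            continue
        mean_power = power[sel].mean(axis=0)     # ch x f x frames
        # linear interpolation of each channel/frequency onto the grid
        interp = np.empty(mean_power.shape[:2] + (grid.size,))
        for c in range(mean_power.shape[0]):
            for fi in range(mean_power.shape[1]):
                interp[c, fi] = np.interp(grid, frame_times, mean_power[c, fi])
        if db:
            original = 10.0 * np.log10(np.maximum(interp, 1e-30))
            base = original[:, :, bsel_grid].mean(axis=2)
            values = original - base[:, :, None]
        else:
            original = interp
            base = original[:, :, bsel_grid].mean(axis=2)
            values = original / base[:, :, None]
        out[task] = ERSPMap(values, freqs.copy(), grid.copy(),
                            tuple(baseline), original, base, epochs.montage)
    return out


def band_topography(ersp_maps: dict[str, ERSPMap],
                    band: tuple[float, float] = (8.0, 13.0),
                    window: tuple[float, float] = (-0.5, 0.5),
                    ) -> dict[str, np.ndarray]:
    """Mean ERSP over a frequency band and time window, per channel and task.

    The default windows (-0.5, 0.5) and (0.5, 1.5) s cover the first and
    second sub-action of a trial respectively.
    """
    out = {}
    for task, m in ersp_maps.items():
        fsel = (m.freqs >= band[0]) & (m.freqs <= band[1])
        tsel = (m.times >= window[0]) & (m.times <= window[1])
        if not fsel.any() or not tsel.any():
            raise ValueError(
                f"empty band/window selection ({band} Hz, {window} s)")
        out[task] = m.values[:, fsel][:, :, tsel].mean(axis=(1, 2))
    return out
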