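"""Filtering, referencing, resampling, trial rejection and automated
ICA-based ocular-artifact removal.

All filters are applied along the time axis and work on either a
:class:`~seqmotor.core_io.ContinuousRecording` or an
:class:`~seqmotor.core_io.EpochSet`.  "4th-order zero-phase Butterworth"
means a 4th-order design applied forward-backward (so the magnitude
response is effectively 8th order); a "0-X Hz" low-pass is a plain low-pass
at X Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core_io import (
    TASK_KEYS,
    ContinuousRecording,
    EpochSet,
    Event,
    EventCode,
    group_trials,
    logger,
)


def _apply(obj, func):
    """Apply ``func`` to the data array of a recording or epoch set."""
    if isinstance(obj, ContinuousRecording):
        return obj.copy_with(data=func(obj.data))
    if isinstance(obj, EpochSet):
        return obj.copy_with(data=func(obj.data))
    raise TypeError(f"expected ContinuousRecording or EpochSet, got {type(obj)}")


def _rate_of(obj) -> float:
    return obj.rate


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------

def notch_filter(obj, freq: float = 50.0, q: float = 30.0):
    """Zero-phase second-order IIR notch at ``freq`` Hz (quality factor Q)."""
    rate = _rate_of(obj)
    if freq >= rate / 2.0:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist ({rate / 2} Hz)")
    b, a = signal.iirnotch(freq, q, fs=rate)
    return _apply(obj, lambda d: signal.filtfilt(b, a, d, axis=-1))


def butterworth_filter(obj, low: float | None = None, high: float | None = None,
                       order: int = 4, zero_phase: bool = True):
    """Butterworth filter: ``low`` = high-pass edge, ``high`` = low-pass edge.

    Passing both gives a band-pass.  ``zero_phase`` applies the design
    forward-backward (sosfiltfilt), removing group delay.
    """
    rate = _rate_of(obj)
    nyq = rate / 2.0
    if low is None and high is None:
        raise ValueError("at least one of low/high must be set")
    for edge in (low, high):
        if edge is not None and not 0.0 < edge < nyq:
            raise ValueError(f"cutoff {edge} Hz outside (0, {nyq}) Hz")
    if low is not None and high is not None:
        sos = signal.butter(order, [low, high], btype="bandpass", fs=rate,
                            output="sos")
    elif high is not None:
        sos = signal.butter(order, high, btype="lowpass", fs=rate, output="sos")
    else:
        sos = signal.butter(order, low, btype="highpass", fs=rate, output="sos")
    if zero_phase:
        return _apply(obj, lambda d: signal.sosfiltfilt(sos, d, axis=-1))
    return _apply(obj, lambda d: signal.sosfilt(sos, d, axis=-1))


def _rescale_sample(sample: int, ratio: Fraction) -> int:
    """Round-half-away-from-zero rescaling of a non-negative sample index."""
    x = sample * ratio.numerator / ratio.denominator
    return int(np.floor(x + 0.5))


def resample(obj, target_rate: float, allow_upsampling: bool = True):
    """Polyphase resampling (anti-alias filtered) with event index rescaling."""
    rate = _rate_of(obj)
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > rate and not allow_upsampling:
        raise ValueError(f"upsampling {rate} -> {target_rate} Hz not allowed")
    ratio = (Fraction(int(round(target_rate * 1000)), 1000)
             / Fraction(int(round(rate * 1000)), 1000))
    up, down = ratio.numerator, ratio.denominator
    if up == down:
        return _apply(obj, lambda d: d.copy())
    if isinstance(obj, ContinuousRecording):
        data = signal.resample_poly(obj.data, up, down, axis=-1)
        events = [Event(_rescale_sample(e.sample, ratio), e.code, e.task)
                  for e in obj.events]
        events = [e for e in events if e.sample < data.shape[-1]]
        return obj.copy_with(data=data, rate=float(target_rate), events=events)
    if isinstance(obj, EpochSet):
        data = signal.resample_poly(obj.data, up, down, axis=-1)
        n_expected = int(round((obj.tmax - obj.tmin) * target_rate))
        data = data[..., :n_expected]
        return obj.copy_with(data=data, rate=float(target_rate))
    raise TypeError(f"expected ContinuousRecording or EpochSet, got {type(obj)}")


def common_average_reference(obj):
    """Subtract the instantaneous mean over channels (CAR)."""
    n_ch = obj.data.shape[-2]
    if n_ch < 2:
        raise ValueError("CAR needs at least 2 channels")
    out = _apply(obj, lambda d: d - d.mean(axis=-2, keepdims=True))
    if isinstance(out, ContinuousRecording):
        out.reference = "CAR"
    return out


# --------------------------------------------------------------------------
# behavioral trial rejection
# --------------------------------------------------------------------------

def reject_bad_trials(events, rate: float, max_gap: float = 2.0
                      ) -> tuple[list[int], list[tuple[int, str]]]:
    """Apply the behavioral rejection rule to an event stream.

    A trial is dropped iff its key codes contradict the task's expected
    sequence, the two keystrokes are separated by more than ``max_gap``
    seconds, or it does not contain exactly two key events.

    Returns ``(kept_trial_ids, [(dropped_id, reason), ...])``.
    """
    kept: list[int] = []
    dropped: list[tuple[int, str]] = []
    for trial in group_trials(events):
        keys = [e for e in trial.key_events
                if e.code in (EventCode.KEY_LEFT, EventCode.KEY_RIGHT)]
        if len(keys) != 2:
            dropped.append((trial.index, "malformed"))
            continue
        expected = TASK_KEYS.get(trial.task)
        got = tuple(e.code.value for e in keys)
        if expected is None or got != expected:
            dropped.append((trial.index, "wrong keys"))
            continue
        gap = (keys[1].sample - keys[0].sample) / rate
        if gap > max_gap:
            dropped.append((trial.index, f"key separation {gap:.2f} s > {max_gap} s"))
            continue
        kept.append(trial.index)
    for idx, reason in dropped:
        logger.info("reject_bad_trials: dropped trial %d (%s)", idx, reason)
    return kept, dropped


# --------------------------------------------------------------------------
# ICA artifact removal (automated surrogate for manual component review)
# --------------------------------------------------------------------------

@dataclass
class ArtifactDecomposition:
    """Linear decomposition X = A S with the removed component indices."""

    mixing: np.ndarray      # channels x components (A)
    unmixing: np.ndarray    # components x channels (W)
    sources: np.ndarray     # components x samples (Y, estimate of S)
    removed: list[int]


def ica_artifact_removal(rec: ContinuousRecording, n_components: int = 20,
                         criterion: str = "eog_correlation",
                         eog_reference=None, threshold: float = 0.8,
                         seed: int = 0,
                         ) -> tuple[ContinuousRecording, ArtifactDecomposition]:
    """Remove artifact components from a recording by FastICA.

    ``eog_correlation`` zeroes every component whose absolute Pearson
    correlation with the EOG reference (a channel name or a 1-D regressor,
    e.g. the simulator's ground-truth blink trace) exceeds ``threshold``.
    ``variance_threshold`` zeroes components whose share of total source
    variance exceeds ``threshold``.
    """
    from sklearn.decomposition import FastICA

    if n_components > rec.n_channels:
        raise ValueError("n_components cannot exceed the channel count")
    if rec.n_samples < 25 * n_components:
        raise ValueError(
            f"recording too short for {n_components} components "
            f"(need >= {25 * n_components} samples)"
        )
    if criterion == "eog_correlation":
        if eog_reference is None:
            raise ValueError("eog_correlation criterion needs an EOG reference")
        if isinstance(eog_reference, str):
            reference = rec.data[rec.montage.index(eog_reference)]
        else:
            reference = np.asarray(eog_reference, dtype=float)
            if reference.shape != (rec.n_samples,):
                raise ValueError("EOG regressor length must match the recording")
    elif criterion == "variance_threshold":
        reference = None
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    ica = FastICA(n_components=n_components, whiten="unit-variance",
                  max_iter=1000, tol=1e-4, random_state=seed)
    sources = ica.fit_transform(rec.data.T)          # samples x components
    mixing = ica.mixing_                             # channels x components
    unmixing = ica.components_                       # components x channels
    mean = ica.mean_

    if criterion == "eog_correlation":
        ref = reference - reference.mean()
        denom = np.linalg.norm(ref)
        corrs = np.zeros(n_components)
        if denom > 0:
            src = sources - sources.mean(axis=0)
            norms = np.linalg.norm(src, axis=0)
            ok = norms > 0
            corrs[ok] = (src[:, ok].T @ ref) / (norms[ok] * denom)
        removed = [int(i) for i in np.flatnonzero(np.abs(corrs) > threshold)]
    else:
        # variance each component contributes to the sensor reconstruction
        contrib = (sources.var(axis=0) * (mixing ** 2).sum(axis=0))
        share = contrib / contrib.sum() if contrib.sum() > 0 else contrib
        removed = [int(i) for i in np.flatnonzero(share > threshold)]

    # subtract only the removed components so the out-of-subspace residual
    # is untouched; zero removed components is then the exact identity
    if removed:
        cleaned = rec.data - (sources[:, removed] @ mixing[:, removed].T).T
    else:
        cleaned = rec.data.copy()
    logger.info("ica_artifact_removal: removed %d/%d components (%s)",
                len(removed), n_components, criterion)
    decomp = ArtifactDecomposition(mixing=mixing, unmixing=unmixing,
                                   sources=sources.T, removed=removed)
    return rec.copy_with(data=cleaned), decomp
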