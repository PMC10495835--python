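"""Movement-related cortical potential (MRCP) analysis.

The MRCP branch works on heavily low-passed data: the recording is
resampled to 16 Hz, low-pass filtered at 3 Hz (4th-order zero-phase
Butterworth), re-referenced to the common average, and epoched over
[-2, 3) s around the first keystroke.  Grand averages are computed
subjects-first (per-subject task means, then the across-subject mean), and
condition contrasts use a pointwise paired t-test on the subject means with
no multiple-comparison correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import TASKS, ChannelMontage, ContinuousRecording, EpochSet, \
    extract_epochs, logger
from .preprocess import butterworth_filter, common_average_reference, resample


@dataclass
class MrcpResult:
    """Per-task grand-average waveforms on a common time grid."""

    waveforms: dict[str, np.ndarray]       # task -> channels x times (uV)
    times: np.ndarray                      # s, relative to first keystroke
    montage: ChannelMontage
    subject_means: np.ndarray | None = None  # subjects x tasks x ch x times
    task_order: tuple[str, ...] = TASKS


@dataclass
class PointwiseTestResult:
    """Paired t-test at every time point of a condition contrast."""

    t_values: np.ndarray
    p_values: np.ndarray
    sig_mask: np.ndarray
    degenerate: np.ndarray     # zero-variance difference at these points
    alpha: float = 0.05


def mrcp_pipeline(rec: ContinuousRecording, target_rate: float = 16.0,
                  lowpass: float = 3.0, tmin: float = -2.0,
                  tmax: float = 3.0) -> EpochSet:
    """Resample -> low-pass -> CAR -> epoch, for MRCP waveform analysis."""
    out = resample(rec, target_rate)
    out = butterworth_filter(out, high=lowpass, order=4, zero_phase=True)
    out = common_average_reference(out)
    return extract_epochs(out, tmin, tmax)


def grand_average(epochs: EpochSet, subjects: np.ndarray | None = None,
                  task_order: tuple[str, ...] = TASKS) -> MrcpResult:
    """Per-task mean waveforms; subjects first when a partition is given.

    Parameters
    ----------
    subjects
        Optional per-trial subject identifier.  When given, trials are
        averaged within subject and task first and the grand average is the
        mean of subject means, which are also returned (the units for the
        paired t-test).
    """
    present = [t for t in task_order if np.any(epochs.labels == t)]
    for t in task_order:
        if t not in present:
            logger.warning("grand_average: no epochs for task %s; excluded", t)
    waveforms: dict[str, np.ndarray] = {}
    subject_means = None
    if subjects is None:
        for task in present:
            waveforms[task] = epochs.data[epochs.labels == task].mean(axis=0)
    else:
        subjects = np.asarray(subjects)
        subj_ids = sorted(set(subjects.tolist()))
        sm = np.full((len(subj_ids), len(present),
                      epochs.n_channels, epochs.n_samples), np.nan)
        for si, s in enumerate(subj_ids):
            for ti, task in enumerate(present):
                sel = (subjects == s) & (epochs.labels == task)
                if sel.any():
                    sm[si, ti] = epochs.data[sel].mean(axis=0)
        subject_means = sm
        for ti, task in enumerate(present):
            waveforms[task] = np.nanmean(sm[:, ti], axis=0)
    return MrcpResult(waveforms, epochs.times, epochs.montage,
                      subject_means=subject_means,
                      task_order=tuple(present))


def pointwise_paired_ttest(cond_a: np.ndarray, cond_b: np.ndarray,
                           alpha: float = 0.05,
                           bonferroni: bool = False) -> PointwiseTestResult:
    """Two-sided paired t-test at each time point over subjects.

    ``cond_a``/``cond_b`` are subjects x time arrays of subject means.
    Zero-variance differences yield t = 0, p = 1 and a degenerate flag.
    A Bonferroni option (off by default) divides alpha by the number of
    time points.
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must share subjects and time grid")
    if a.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    d = a - b
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0
    t_vals = np.zeros(d.shape[1])
    np.divide(mean, sd / np.sqrt(n), out=t_vals, where=~degenerate)
    p_vals = np.ones(d.shape[1])
    p_vals[~degenerate] = 2.0 * stats.t.sf(np.abs(t_vals[~degenerate]), n - 1)
    level = alpha / d.shape[1] if bonferroni else alpha
    mask = p_vals < level
    mask[degenerate] = False
    return PointwiseTestResult(t_vals, p_vals, mask, degenerate, alpha=alpha)


def topography_at(result: MrcpResult,
                  times: tuple[float, ...] = (-0.150, 0.850),
                  ) -> dict[str, dict[float, np.ndarray]]:
    """Per-task channel values at the grid point nearest each requested time.

    Returns ``{task: {actual_grid_time: channel_values}}``; the key is the
    snapped grid time actually used, not the requested one.
    """
    out: dict[str, dict[float, np.ndarray]] = {}
    grid = result.times
    for t_req in times:
        if not grid[0] <= t_req <= grid[-1]:
            raise ValueError(f"time {t_req} s outside epoch window "
                             f"[{grid[0]}, {grid[-1]}] s")
    for task, wave in result.waveforms.items():
        out[task] = {}
        for t_req in times:
            idx = int(np.argmin(np.abs(grid - t_req)))
            out[task][float(grid[idx])] = wave[:, idx].copy()
    return out
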