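"""Paradigm-faithful synthetic EEG for the sequential keystroke experiment.

The generator reproduces the statistical structure the downstream analysis
assumes rather than a biophysical forward model:

* a protocol of cued trials, each with two keystrokes about 1 s apart,
  task-balanced within 60-trial blocks (LL/RR/LR/RL, 15 each);
* a movement-related cortical potential per keystroke: a negative linear
  ramp starting before the key press, peaking at the press, with a
  half-cosine rebound — projected onto hand-area channels with
  contralateral dominance (left finger -> C4 side, right finger -> C3 side);
* ongoing alpha and beta oscillations whose amplitude is attenuated
  (event-related desynchronization) in a window around each keystroke,
  with the same contralateral weighting;
* 1/f background noise, common-mode 50 Hz line interference and optional
  frontal blink artifacts.

Oscillation phase is locked to the first keystroke of each trial so that,
with jitter and noise switched off, trial averaging recovers the class
template exactly; trial-averaged spectral power is unaffected by this
choice.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    TASKS,
    TASK_KEYS,
    ChannelMontage,
    ContinuousRecording,
    Event,
    EventCode,
    group_trials,
    logger,
    standard_montage,
)

# trial timeline (s): ready circle, prompt-to-first-key delay, inter-key
# interval, post-keystroke rest — giving a ~6 s first-key-to-first-key stride
READY_DUR = 1.0
PROMPT_DELAY = 2.0
PROMPT_JITTER = 0.1          # uniform, +- s
KEY_INTERVAL = 1.0
REST_DUR = 2.0
LEAD_IN = 4.0                # recording padding before the first cue
LEAD_OUT = 4.0


@dataclass(frozen=True)
class TrialSpec:
    task: str
    cue_onset: float
    key1: float
    key2: float


@dataclass
class ProtocolSchedule:
    """Blocks of timed trials; times are absolute seconds in the recording."""

    blocks: list[list[TrialSpec]]

    @property
    def trials(self) -> list[TrialSpec]:
        return [t for b in self.blocks for t in b]

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    def task_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in TASKS}
        for tr in self.trials:
            counts[tr.task] += 1
        return counts

    def block_ids(self) -> np.ndarray:
        """Per-trial 1-based block index, in trial order."""
        return np.concatenate(
            [np.full(len(b), i + 1) for i, b in enumerate(self.blocks)]
        ) if self.blocks else np.empty(0, int)


@dataclass(frozen=True)
class SignalModelParams:
    """Amplitudes/timings of the simulated EEG phenomena (uV, s, Hz)."""

    mrcp_peak_amp: float = -8.0        # uV, <= 0
    mrcp_rise_start: float = 1.5       # s before the keystroke
    mrcp_rebound: float = 0.5          # s half-cosine return to baseline
    second_key_scale: float = 0.8      # repeated sub-action second-key scale
    contralateral_ratio: float = 2.0   # contra vs ipsi hand-area weighting
    erd_alpha_depth: float = 0.5       # amplitude attenuation in [0, 1]
    erd_beta_depth: float = 0.3
    erd_window: float = 1.0            # s, centered on each keystroke
    alpha_freq: float = 10.0
    beta_freq: float = 20.0
    alpha_amp: float = 5.0             # uV ongoing oscillation amplitude
    beta_amp: float = 2.0
    noise_scale: float = 4.0           # uV RMS of 1/f background
    line_amp: float = 2.0              # uV 50 Hz common-mode interference
    line_freq: float = 50.0
    eog_rate: float = 0.0              # blinks per minute (0 = off)
    eog_amp: float = 120.0             # uV blink peak
    spatial_spread: float = 0.045      # m Gaussian kernel decay on the scalp
    key_jitter: float = 0.05           # s SD of inter-key interval jitter
    key_jitter_max: float = 0.15       # truncation bound

    def __post_init__(self):
        if self.mrcp_peak_amp > 0:
            raise ValueError("mrcp_peak_amp must be <= 0 (a negativity)")
        for name in ("erd_alpha_depth", "erd_beta_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.erd_window <= 0:
            raise ValueError("erd_window must be positive")
        for name in ("alpha_amp", "beta_amp", "noise_scale", "line_amp",
                     "eog_amp", "spatial_spread", "contralateral_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# --------------------------------------------------------------------------
# protocol
# --------------------------------------------------------------------------

def _timed_trials(tasks: list[str], rng: np.random.Generator, t0: float,
                  jitter_sd: float, jitter_max: float,
                  prompt_jitter: float) -> tuple[list[TrialSpec], float]:
    trials = []
    t = t0
    for task in tasks:
        cue = t
        prompt_jit = (rng.uniform(-prompt_jitter, prompt_jitter)
                      if prompt_jitter > 0 else 0.0)
        key1 = cue + READY_DUR + PROMPT_DELAY + prompt_jit
        jit = np.clip(rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0,
                      -jitter_max, jitter_max)
        key2 = key1 + KEY_INTERVAL + jit
        trials.append(TrialSpec(task, cue, key1, key2))
        t = key2 + REST_DUR
    return trials, t


def make_protocol(n_blocks: int = 10, trials_per_block: int = 60,
                  tasks: tuple[str, ...] = TASKS, seed: int = 0,
                  key_jitter: float = 0.05,
                  key_jitter_max: float = 0.15,
                  prompt_jitter: float = PROMPT_JITTER) -> ProtocolSchedule:
    """Task-balanced offline protocol: each task occurs equally often per block."""
    if trials_per_block % len(tasks) != 0:
        raise ValueError(
            f"trials_per_block={trials_per_block} not divisible by "
            f"{len(tasks)} tasks"
        )
    rng = np.random.default_rng(seed)
    per = trials_per_block // len(tasks)
    blocks = []
    t = LEAD_IN
    for _ in range(n_blocks):
        order = list(rng.permutation(np.repeat(list(tasks), per)))
        block, t = _timed_trials(order, rng, t, key_jitter, key_jitter_max,
                                 prompt_jitter)
        blocks.append(block)
        t += REST_DUR  # short inter-block pause
    return ProtocolSchedule(blocks)


def make_online_protocol(seed: int = 0, key_jitter: float = 0.05,
                         key_jitter_max: float = 0.15,
                         prompt_jitter: float = PROMPT_JITTER) -> ProtocolSchedule:
    """Eight-block online protocol: 6 offline-style blocks (360 trials,
    90 per task) plus a 40-trial LL/RR block and a 40-trial LR/RL block."""
    rng = np.random.default_rng(seed)
    blocks = []
    t = LEAD_IN
    for _ in range(6):
        order = list(rng.permutation(np.repeat(list(TASKS), 15)))
        block, t = _timed_trials(order, rng, t, key_jitter, key_jitter_max,
                                 prompt_jitter)
        blocks.append(block)
        t += REST_DUR
    for pair in (("LL", "RR"), ("LR", "RL")):
        order = list(rng.permutation(np.repeat(list(pair), 20)))
        block, t = _timed_trials(order, rng, t, key_jitter, key_jitter_max,
                                 prompt_jitter)
        blocks.append(block)
        t += REST_DUR
    return ProtocolSchedule(blocks)


# --------------------------------------------------------------------------
# signal model
# --------------------------------------------------------------------------

def _hand_pattern(montage: ChannelMontage, hand: str,
                  params: SignalModelParams) -> np.ndarray:
    """Spatial weights for one moving hand: Gaussian kernel centered on the
    contralateral hand area (C4 for left, C3 for right), plus an
    ipsilateral kernel down-weighted by the contralateral ratio."""
    contra = "C4" if hand == "L" else "C3"
    ipsi = "C3" if hand == "L" else "C4"
    pos = montage.positions
    s2 = 2.0 * params.spatial_spread ** 2

    def kernel(center: str) -> np.ndarray:
        d2 = np.sum((pos - pos[montage.index(center)]) ** 2, axis=1)
        return np.exp(-d2 / s2)

    w = kernel(contra) + kernel(ipsi) / params.contralateral_ratio
    return w / w.max()


def _mrcp_waveform(t: np.ndarray, key_time: float, amp: float,
                   params: SignalModelParams) -> np.ndarray:
    """Negative ramp from key_time - rise_start to key_time, then a
    half-cosine rebound to baseline over ``mrcp_rebound`` seconds."""
    w = np.zeros_like(t)
    rise = (t >= key_time - params.mrcp_rise_start) & (t < key_time)
    w[rise] = amp * (t[rise] - (key_time - params.mrcp_rise_start)) / params.mrcp_rise_start
    reb = (t >= key_time) & (t < key_time + params.mrcp_rebound)
    w[reb] = amp * 0.5 * (1.0 + np.cos(np.pi * (t[reb] - key_time) / params.mrcp_rebound))
    return w


def _trial_keystrokes(trial: TrialSpec, params: SignalModelParams
                      ) -> list[tuple[float, str, float]]:
    """(time, hand, amplitude) per keystroke; the second keystroke of a
    repeated sub-action task is scaled down (habituation of the peak)."""
    h1, h2 = trial.task[0], trial.task[1]
    a1 = params.mrcp_peak_amp
    a2 = a1 * (params.second_key_scale if h1 == h2 else 1.0)
    return [(trial.key1, h1, a1), (trial.key2, h2, a2)]


def _pink_noise(rng: np.random.Generator, n: int, rate: float,
                rms: float) -> np.ndarray:
    """1/f-amplitude noise with the requested RMS (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    spec /= np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def simulate_dataset(schedule: ProtocolSchedule,
                     params: SignalModelParams | None = None,
                     montage: ChannelMontage | None = None,
                     rate: float = 1000.0,
                     seed: int = 0) -> ContinuousRecording:
    """Render a protocol into a continuous multichannel recording.

    The returned recording carries a ``ground_truth`` dict with the
    per-trial keystroke times, the deterministic spatial patterns, the
    blink time course (if any) and an initially empty bad-trial list.
    """
    params = params or SignalModelParams()
    montage = montage or standard_montage()
    montage.require_sensorimotor()
    if rate < 2.0 * params.beta_freq:
        raise ValueError(
            f"rate {rate} Hz cannot represent the {params.beta_freq} Hz "
            "beta band (need rate >= 2 x beta_freq)"
        )
    rng = np.random.default_rng(seed)
    trials = schedule.trials
    if not trials:
        raise ValueError("empty protocol")
    n = int(round((trials[-1].key2 + LEAD_OUT) * rate))
    n_ch = len(montage)
    t_axis = np.arange(n) / rate
    data = np.zeros((n_ch, n))

    patterns = {h: _hand_pattern(montage, h, params) for h in ("L", "R")}
    phase = 2.0 * np.pi * np.arange(n_ch) / n_ch  # deterministic per channel

    # deterministic evoked + induced structure, trial by trial
    key1_samples = np.array([int(round(tr.key1 * rate)) for tr in trials])
    bounds = np.concatenate([[0], key1_samples[1:] - int(round(2.5 * rate)), [n]])
    for k, trial in enumerate(trials):
        keystrokes = _trial_keystrokes(trial, params)
        i0, i1 = int(bounds[k]), int(bounds[k + 1])
        tt = t_axis[i0:i1]
        # MRCP templates
        for key_time, hand, amp in keystrokes:
            wave = _mrcp_waveform(tt, key_time, amp, params)
            data[:, i0:i1] += np.outer(patterns[hand], wave)
        # oscillations with keystroke-locked ERD
        rel = tt - trial.key1
        for freq, amp, depth in (
            (params.alpha_freq, params.alpha_amp, params.erd_alpha_depth),
            (params.beta_freq, params.beta_amp, params.erd_beta_depth),
        ):
            if amp == 0:
                continue
            base = np.cos(2.0 * np.pi * freq * rel[None, :] + phase[:, None])
            suppression = np.zeros((n_ch, i1 - i0))
            for key_time, hand, _ in keystrokes:
                inside = np.abs(tt - key_time) <= params.erd_window / 2.0
                np.maximum(suppression,
                           depth * np.outer(patterns[hand], inside),
                           out=suppression)
            data[:, i0:i1] += amp * (1.0 - suppression) * base

    # 1/f background noise
    if params.noise_scale > 0:
        for ch in range(n_ch):
            data[ch] += _pink_noise(rng, n, rate, params.noise_scale)

    # common-mode line interference
    if params.line_amp > 0:
        line_phase = rng.uniform(0, 2 * np.pi)
        data += params.line_amp * np.sin(
            2.0 * np.pi * params.line_freq * t_axis + line_phase)[None, :]

    # frontal blink artifacts
    blink_trace = np.zeros(n)
    if params.eog_rate > 0:
        frontal = [c for c in ("Fp1", "Fpz", "Fp2") if c in montage.names]
        if not frontal:
            raise ValueError("eog_rate > 0 requires frontal (Fp*) channels")
        center = np.mean([montage.positions[montage.index(c)] for c in frontal],
                         axis=0)
        d2 = np.sum((montage.positions - center) ** 2, axis=1)
        eog_pattern = np.exp(-d2 / (2.0 * params.spatial_spread ** 2))
        blink_dur = 0.4
        n_blink = int(round(blink_dur * rate))
        template = np.sin(np.pi * np.arange(n_blink) / n_blink) ** 2
        n_blinks = rng.poisson(params.eog_rate * (n / rate) / 60.0)
        onsets = rng.uniform(0, n / rate - blink_dur, size=n_blinks)
        for onset in np.sort(onsets):
            j = int(round(onset * rate))
            blink_trace[j : j + n_blink] += params.eog_amp * template
        data += np.outer(eog_pattern, blink_trace)

    # events
    events: list[Event] = []
    for trial in trials:
        events.append(Event(int(round(trial.cue_onset * rate)),
                            EventCode.TRIAL_START, trial.task))
        for key_time, hand, _ in _trial_keystrokes(trial, params):
            code = EventCode.KEY_LEFT if hand == "L" else EventCode.KEY_RIGHT
            events.append(Event(int(round(key_time * rate)), code))

    ground_truth = {
        "params": params,
        "patterns": patterns,
        "key_times": [(tr.key1, tr.key2) for tr in trials],
        "tasks": [tr.task for tr in trials],
        "block_ids": schedule.block_ids(),
        "blink_trace": blink_trace if params.eog_rate > 0 else None,
        "bad_trials": [],
    }
    logger.info("simulate_dataset: %d trials, %d channels, %.1f s at %g Hz",
                len(trials), n_ch, n / rate, rate)
    return ContinuousRecording(data, rate, montage, events,
                               reference="nose", ground_truth=ground_truth)


def inject_bad_trials(rec: ContinuousRecording, fraction: float,
                      seed: int = 0) -> tuple[ContinuousRecording, list[int]]:
    """Corrupt a seed-chosen subset of trials so the rejection rule fires.

    Half of the chosen trials (alternating) get a wrong first-key code, the
    rest get their second keystroke delayed beyond the 2 s limit.  Returns
    the modified recording and the ground-truth bad-trial index list.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    trials = group_trials(rec.events)
    n_bad = int(round(fraction * len(trials)))
    if n_bad == 0:
        return rec, []
    rng = np.random.default_rng(seed)
    bad_ids = sorted(rng.choice(len(trials), size=n_bad, replace=False))

    flip = {EventCode.KEY_LEFT: EventCode.KEY_RIGHT,
            EventCode.KEY_RIGHT: EventCode.KEY_LEFT}
    new_events: dict[int, Event] = {id(e): e for t in trials for e in t.key_events}
    replacements: dict[Event, Event] = {}
    for j, tid in enumerate(bad_ids):
        keys = [e for e in trials[tid].key_events]
        if len(keys) < 2:
            continue
        if j % 2 == 0:  # wrong key press
            replacements[keys[0]] = replace(keys[0], code=flip[keys[0].code])
        else:           # delayed second keystroke (> 2 s separation)
            gap = rng.uniform(2.05, 2.35)
            new_sample = keys[0].sample + int(round(gap * rec.rate))
            replacements[keys[1]] = replace(keys[1], sample=new_sample)
    events = sorted((replacements.get(e, e) for e in rec.events),
                    key=lambda e: e.sample)
    gt = dict(rec.ground_truth or {})
    gt["bad_trials"] = list(bad_ids)
    out = rec.copy_with(events=events, ground_truth=gt)
    logger.info("inject_bad_trials: corrupted %d/%d trials", n_bad, len(trials))
    return out, list(bad_ids)
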