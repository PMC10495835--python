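"""Core data model and I/O for sequential finger-movement EEG analysis.

Conventions used throughout the package:

* all times are seconds, all amplitudes microvolts;
* channel order is montage order everywhere;
* epoch windows follow the half-open convention ``[tmin, tmax)`` so the
  sample count is ``round((tmax - tmin) * rate)`` at every sampling rate;
* time 0 of an epoch is the first keystroke of the trial.

Continuous data travel either as EDF (16-bit, with a tab-delimited events
sidecar) or as a delimited triplet ``<stem>.data.tsv`` / ``<stem>.meta.yaml``
/ ``<stem>.events.tsv``.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger("seqmotor")

#: the four sequential finger-movement tasks (first letter = first keystroke)
TASKS = ("LL", "RR", "LR", "RL")

#: expected key-event sequence per task
TASK_KEYS = {
    "LL": ("KEY_LEFT", "KEY_LEFT"),
    "RR": ("KEY_RIGHT", "KEY_RIGHT"),
    "LR": ("KEY_LEFT", "KEY_RIGHT"),
    "RL": ("KEY_RIGHT", "KEY_LEFT"),
}


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

#: every pipeline parameter, overridable from a YAML file
DEFAULT_CONFIG: dict = {
    "rate": 1000.0,
    "notch_freq": 50.0,
    "notch_q": 30.0,
    "mrcp": {"target_rate": 16.0, "lowpass": 3.0, "tmin": -2.0, "tmax": 3.0,
             "topo_times": [-0.150, 0.850]},
    "ersp": {"target_rate": 200.0, "band": [4.0, 30.0], "window_len": 256,
             "hop": 64, "trange": [-1.5, 2.5], "baseline": [-1.5, -1.0],
             "alpha_band": [8.0, 13.0],
             "subaction_windows": [[-0.5, 0.5], [0.5, 1.5]]},
    "features": {"target_rate": 200.0, "tmin": -0.5, "tmax": 1.5,
                 "mrcp_band": [1.0, 8.0],
                 "bands": [[4.0, 8.0], [8.0, 13.0], [13.0, 30.0]],
                 "n_dsp": 2, "n_trca": 3, "n_csp": 3, "shrinkage": 0.05},
    "decode": {"C": 1.0, "folds": 10, "k_features": 10, "n_bins": 10},
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML configuration merged over :data:`DEFAULT_CONFIG`."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"configuration in {path} must be a mapping")
        cfg = _deep_update(cfg, user)
    return _deep_update({}, cfg)  # deep copy


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelMontage:
    """Ordered scalp montage: 10-20 labels plus 2-D positions.

    Positions are the x/y head-frame coordinates (meters, nose = +y) used
    for topography export and for spatial kernels in the simulator.
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise ValueError("montage channel names must be unique")
        if pos.shape != (len(names), 2):
            raise ValueError(f"positions must be ({len(names)}, 2), got {pos.shape}")
        if not np.isfinite(pos).all():
            raise ValueError("montage positions must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def require_sensorimotor(self) -> None:
        missing = [c for c in ("C3", "Cz", "C4") if c not in self.names]
        if missing:
            raise ValueError(f"montage lacks sensorimotor channels: {missing}")


#: the full 60-channel 10-20 layout of the recording setup
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

#: a reduced sensorimotor-focused subset for fast runs
MOTOR_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CPz", "CP4",
    "P3", "Pz", "P4",
)


def standard_montage(names: Sequence[str] | None = None) -> ChannelMontage:
    """Build a :class:`ChannelMontage` from the standard 10-20/10-05 layout.

    Parameters
    ----------
    names
        Channel labels to include, in order.  Defaults to the full
        60-channel layout (:data:`DEFAULT_CHANNELS`).
    """
    import warnings

    import mne

    if names is None:
        names = DEFAULT_CHANNELS
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1005")
    pos3d = std.get_positions()["ch_pos"]
    missing = [n for n in names if n not in pos3d]
    if missing:
        raise KeyError(f"labels not in the standard 10-05 layout: {missing}")
    xy = np.array([pos3d[n][:2] for n in names], dtype=float)
    return ChannelMontage(tuple(names), xy)


class EventCode(str, Enum):
    TRIAL_START = "TRIAL_START"
    KEY_LEFT = "KEY_LEFT"
    KEY_RIGHT = "KEY_RIGHT"


@dataclass(frozen=True)
class Event:
    """One timestamped marker; ``task`` is set on TRIAL_START events only."""

    sample: int
    code: EventCode
    task: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "code", EventCode(self.code))
        if self.sample < 0:
            raise ValueError("event sample must be non-negative")
        if self.task is not None and self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class ContinuousRecording:
    """Channels x samples EEG in microvolts plus an ordered event stream."""

    data: np.ndarray
    rate: float
    montage: ChannelMontage
    events: list[Event] = field(default_factory=list)
    reference: str = "nose"
    ground_truth: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{len(self.montage)} channels"
            )
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        self.events = list(self.events)
        samples = [e.sample for e in self.events]
        if samples != sorted(samples):
            raise ValueError("events must be sorted by sample")
        if samples and samples[-1] >= self.n_samples:
            raise ValueError(
                f"event at sample {samples[-1]} beyond recording "
                f"length {self.n_samples}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, **kw) -> "ContinuousRecording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Trials x channels x samples tensor time-locked to the first keystroke."""

    data: np.ndarray
    labels: np.ndarray  # per-trial task strings
    tmin: float
    tmax: float
    rate: float
    montage: ChannelMontage
    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        expected = int(round((self.tmax - self.tmin) * self.rate))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != round((tmax-tmin)*rate)"
                f" = {expected}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.rate

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# trial grouping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """Events of one trial: the TRIAL_START marker and its key events."""

    index: int
    task: str
    start_sample: int
    key_events: tuple[Event, ...]


def group_trials(events: Iterable[Event]) -> list[Trial]:
    """Group a flat event stream into trials.

    A trial is a TRIAL_START (carrying the task label) followed by the key
    events up to the next TRIAL_START.
    """
    trials: list[Trial] = []
    current: list[Event] | None = None
    start: Event | None = None
    for ev in events:
        if ev.code is EventCode.TRIAL_START:
            if start is not None:
                trials.append(Trial(len(trials), start.task, start.sample,
                                    tuple(current)))
            start, current = ev, []
        elif start is not None:
            current.append(ev)
    if start is not None:
        trials.append(Trial(len(trials), start.task, start.sample, tuple(current)))
    return trials


# --------------------------------------------------------------------------
# delimited + events format
# --------------------------------------------------------------------------

def _delimited_paths(path: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(path)
    return (stem.with_suffix(".data.tsv"), stem.with_suffix(".meta.yaml"),
            stem.with_suffix(".events.tsv"))


def _write_events_tsv(path: Path, events: Sequence[Event]) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcode\ttask\n")
        for ev in events:
            fh.write(f"{ev.sample}\t{ev.code.value}\t{ev.task or ''}\n")


def _read_events_tsv(path: Path) -> list[Event]:
    events: list[Event] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["sample", "code", "task"]:
            raise ValueError(f"unexpected events header {header} in {path}")
        for line in fh:
            if not line.strip():
                continue
            sample, code, task = (line.rstrip("\n").split("\t") + [""])[:3]
            events.append(Event(int(sample), EventCode(code), task or None))
    return events


# --------------------------------------------------------------------------
# minimal EDF writer (16-bit); reading goes through MNE
# --------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if isinstance(value, float):
        s = f"{value:.10g}"
        if len(s) > width:  # fall back to reduced precision
            s = f"{value:.{max(width - 7, 1)}e}"
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _edf_bound(value: float, up: bool) -> float:
    """Round a physical bound outward to a value an 8-char EDF header field
    represents exactly, so writer and readers use identical scaling."""
    margin = max(abs(value), 1e-3) * 1e-5
    while True:
        v2 = value + margin if up else value - margin
        for prec in range(7, 0, -1):
            s = f"{v2:.{prec}g}"
            if len(s) <= 8:
                break
        q = float(s)
        if (q >= value) if up else (q <= value):
            return q
        margin *= 10.0


def _write_edf(path: Path, rec: ContinuousRecording) -> None:
    # one data record per second; the tail is zero-padded to a whole record
    if abs(rec.rate - round(rec.rate)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(rec.rate))            # samples per record per channel
    n_rec = int(np.ceil(rec.n_samples / spr))
    n_ch = rec.n_channels
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data

    # physical bounds quantized to header precision so writer and readers
    # use the identical scaling; widened so no sample falls outside
    pmin = np.array([_edf_bound(v, up=False) for v in data.min(axis=1)])
    pmax = np.array([_edf_bound(v, up=True) for v in data.max(axis=1)])
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    hdr = io.BytesIO()
    hdr.write(_edf_field(0, 8))
    hdr.write(_edf_field("seqmotor", 80))                 # patient id
    hdr.write(_edf_field(f"ref:{rec.reference}", 80))     # recording id
    hdr.write(_edf_field("01.01.00", 8))
    hdr.write(_edf_field("00.00.00", 8))
    hdr.write(_edf_field(256 * (n_ch + 1), 8))
    hdr.write(_edf_field("", 44))
    hdr.write(_edf_field(n_rec, 8))
    hdr.write(_edf_field(1, 8))                           # record duration (s)
    hdr.write(_edf_field(n_ch, 4))
    for width, values in (
        (16, rec.montage.names),
        (80, [""] * n_ch),                                # transducer
        (8, ["uV"] * n_ch),
        (8, [float(v) for v in pmin]),
        (8, [float(v) for v in pmax]),
        (8, [dmin] * n_ch),
        (8, [dmax] * n_ch),
        (80, [""] * n_ch),                                # prefiltering
        (8, [spr] * n_ch),
        (32, [""] * n_ch),
    ):
        for v in values:
            hdr.write(_edf_field(v, width))

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(struct.pack(f"<{n_ch * spr}h", *block.ravel()))


def _read_edf(path: Path, montage: ChannelMontage | None) -> ContinuousRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = tuple(raw.ch_names)
    data_uv = raw.get_data() * 1e6        # MNE returns volts
    if montage is None:
        try:
            montage = standard_montage(names)
        except KeyError:
            montage = ChannelMontage(names, np.zeros((len(names), 2)))
    elif tuple(montage.names) != names:
        raise ValueError("EDF channel labels do not match the supplied montage")
    events_path = Path(path).with_suffix(".events.tsv")
    events = _read_events_tsv(events_path) if events_path.exists() else []
    with open(path, "rb") as fh:
        fh.seek(88)   # version(8) + patient id(80)
        rec_id = fh.read(80).decode("ascii", "ignore").strip()
    reference = rec_id.removeprefix("ref:") if rec_id.startswith("ref:") else "other"
    return ContinuousRecording(data_uv, float(raw.info["sfreq"]), montage,
                               events, reference=reference)


# --------------------------------------------------------------------------
# public I/O operations
# --------------------------------------------------------------------------

def save_recording(rec: ContinuousRecording, path: str | Path,
                   format: str = "delimited") -> Path:
    """Write a recording to disk; returns the primary written path.

    ``delimited`` writes ``<stem>.data.tsv`` (samples x channels with a
    header), ``<stem>.meta.yaml`` (rate, units, reference, montage) and
    ``<stem>.events.tsv``.  ``edf`` writes 16-bit EDF plus the events
    sidecar.
    """
    if rec.n_samples == 0:
        raise ValueError("refusing to save an empty recording (0 samples)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        data_p, meta_p, events_p = _delimited_paths(path)
        header = "\t".join(rec.montage.names)
        np.savetxt(data_p, rec.data.T, fmt="%.6f", delimiter="\t",
                   header=header, comments="")
        meta = {
            "rate": float(rec.rate),
            "units": "microvolts",
            "reference": rec.reference,
            "channels": list(rec.montage.names),
            "positions": [[float(x), float(y)] for x, y in rec.montage.positions],
        }
        with open(meta_p, "w") as fh:
            yaml.safe_dump(meta, fh)
        _write_events_tsv(events_p, rec.events)
        return data_p
    if format == "edf":
        if path.suffix != ".edf":
            path = path.with_suffix(".edf")
        _write_edf(path, rec)
        _write_events_tsv(path.with_suffix(".events.tsv"), rec.events)
        return path
    raise ValueError(f"unknown format {format!r} (expected 'delimited' or 'edf')")


def load_recording(path: str | Path, format: str = "delimited",
                   montage: ChannelMontage | None = None) -> ContinuousRecording:
    """Load a recording written by :func:`save_recording` (or any EDF)."""
    path = Path(path)
    if format == "delimited":
        data_p, meta_p, events_p = _delimited_paths(path)
        for p in (data_p, meta_p):
            if not p.exists():
                raise FileNotFoundError(p)
        with open(meta_p) as fh:
            meta = yaml.safe_load(fh)
        with open(data_p) as fh:
            names = tuple(fh.readline().strip().split("\t"))
        if list(names) != list(meta["channels"]):
            raise ValueError("data header and sidecar channel lists disagree")
        if meta.get("units", "microvolts") not in ("microvolts", "uV"):
            raise ValueError(f"unsupported units {meta['units']!r}")
        data = np.loadtxt(data_p, delimiter="\t", skiprows=1, ndmin=2).T
        if montage is None:
            montage = ChannelMontage(names, np.asarray(meta["positions"], float))
        elif tuple(montage.names) != names:
            raise ValueError("file channels do not match the supplied montage")
        events = _read_events_tsv(events_p) if events_p.exists() else []
        return ContinuousRecording(data, float(meta["rate"]), montage, events,
                                   reference=meta.get("reference", "other"))
    if format == "edf":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_edf(path, montage)
    raise ValueError(f"unknown format {format!r} (expected 'delimited' or 'edf')")


def extract_epochs(rec: ContinuousRecording, tmin: float, tmax: float,
                   anchor: str = "first_key") -> EpochSet:
    """Cut epochs time-locked to the first (or second) keystroke per trial.

    Windows use the half-open convention ``[tmin, tmax)``; trials whose
    window leaves the recording are dropped with a logged warning.
    """
    if not tmin < tmax:
        raise ValueError("tmin must be < tmax")
    if anchor not in ("first_key", "second_key"):
        raise ValueError(f"unknown anchor {anchor!r}")
    n_lead = int(round(-tmin * rec.rate))
    n_len = int(round((tmax - tmin) * rec.rate))
    epochs, labels, dropped = [], [], []
    for trial in group_trials(rec.events):
        keys = [e for e in trial.key_events
                if e.code in (EventCode.KEY_LEFT, EventCode.KEY_RIGHT)]
        if not keys or (anchor == "second_key" and len(keys) < 2):
            dropped.append((trial.index, "no anchor key event"))
            continue
        anchor_sample = keys[0 if anchor == "first_key" else 1].sample
        i0 = anchor_sample - n_lead
        if i0 < 0 or i0 + n_len > rec.n_samples:
            dropped.append((trial.index, "window outside recording"))
            continue
        epochs.append(rec.data[:, i0 : i0 + n_len])
        labels.append(trial.task)
    for idx, reason in dropped:
        logger.warning("extract_epochs: dropped trial %d (%s)", idx, reason)
    data = (np.stack(epochs) if epochs
            else np.empty((0, rec.n_channels, n_len)))
    return EpochSet(data, np.array(labels, dtype=object), tmin, tmax,
                    rec.rate, rec.montage, dropped=dropped)
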