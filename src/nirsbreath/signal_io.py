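"""Reading, writing and protocol segmentation of NIRS concentration recordings.

A recording is a set of equal-length, uniformly sampled channels (O2Hb, HHb,
THb in μM change-from-reference; optional TSI in %) with a known sampling
rate. Recordings are exchanged as delimited text with a header row; the
segmentation step slices a recording into the named protocol conditions
(e.g. baseline / loaded breathing / recovery / rapid breathing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nirsbreath")

#: Channel names the pipeline understands.
KNOWN_CHANNELS = ("O2Hb", "HHb", "THb", "TSI")

#: Column order of the window feature matrix on disk.
FEATURE_MATRIX_COLUMNS = (
    "participant",
    "condition",
    "window_index",
    "interval_mean_s",
    "depth_mean",
    "o2hb_amplitude",
    "label",
)


class SignalIOError(ValueError):
    """Raised for malformed recordings, schedules, or files."""


@dataclass
class NirsRecording:
    """Uniformly sampled multi-channel concentration time series.

    Parameters
    ----------
    participant_id :
        Identifier for the participant/session.
    fs :
        Sampling rate in Hz (positive).
    channels :
        Map from channel name (``O2Hb``, ``HHb``, ``THb``, ``TSI``) to
        equal-length 1-D sample vectors. Concentrations are μM change from
        the session reference; TSI is %.
    t0 :
        Start time in seconds (default 0).
    """

    participant_id: str
    fs: float
    channels: dict[str, np.ndarray]
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SignalIOError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise SignalIOError("recording has no channels")
        lengths = {name: len(v) for name, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise SignalIOError(f"channel lengths differ: {lengths}")
        if self.n_samples < 2:
            raise SignalIOError("recording must contain at least 2 samples")
        for name, v in self.channels.items():
            arr = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise SignalIOError(f"channel {name!r} contains non-finite samples")
            self.channels[name] = arr

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        """Duration in seconds, (n-1)/fs (time of the last sample)."""
        return (self.n_samples - 1) / self.fs

    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class ProtocolSchedule:
    """Ordered list of named protocol conditions with durations in seconds.

    ``classification_labels`` names the subset of conditions used as classes
    by the classifier (the remaining conditions are processed but masked).
    """

    stages: Sequence[tuple[str, float]]
    classification_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.stages]
        if len(set(names)) != len(names):
            raise SignalIOError(f"condition names must be unique, got {names}")
        for name, dur in self.stages:
            if dur <= 0:
                raise SignalIOError(f"duration for {name!r} must be > 0, got {dur}")
        unknown = set(self.classification_labels) - set(names)
        if unknown:
            raise SignalIOError(f"classification labels not in schedule: {unknown}")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.stages))

    @property
    def condition_names(self) -> list[str]:
        return [n for n, _ in self.stages]


def default_protocol() -> ProtocolSchedule:
    """The 23-minute five-stage protocol: 3-min baseline, then four 5-min
    stages (loaded breathing, recovery 1, rapid breathing, recovery 2).
    Baseline, loaded and rapid are the classified conditions."""
    return ProtocolSchedule(
        stages=[
            ("baseline", 180.0),
            ("loaded", 300.0),
            ("recovery1", 300.0),
            ("rapid", 300.0),
            ("recovery2", 300.0),
        ],
        classification_labels=("baseline", "loaded", "rapid"),
    )


@dataclass
class ConditionSegment:
    """One labeled contiguous slice of a recording (half-open sample range)."""

    condition_name: str
    start_index: int
    end_index: int
    channels: dict[str, np.ndarray] = field(repr=False)
    fs: float = 10.0

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def read_nirs_csv(
    path: str | Path,
    column_map: Mapping[str, str],
    fs: float,
    participant_id: str | None = None,
    time_column: str | None = "time_s",
) -> NirsRecording:
    """Read a delimited-text recording (CSV or TSV, sniffed automatically).

    Parameters
    ----------
    path :
        File to read.
    column_map :
        Map from file column name to channel name; must map some column to
        ``O2Hb``. Unmapped columns are ignored.
    fs :
        Sampling rate in Hz. If ``time_column`` is present in the file, its
        median increment must agree with ``1/fs`` within 1%.
    participant_id :
        Defaults to the file stem.
    time_column :
        Name of the time column to validate against ``fs`` (skipped if the
        column is absent or this is None).

    Rows containing any non-finite value in a mapped column are dropped with
    a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    if fs <= 0:
        raise SignalIOError(f"sampling rate must be positive, got {fs}")
    if "O2Hb" not in column_map.values():
        raise SignalIOError("column_map must name an O2Hb column")

    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise SignalIOError(f"columns {missing} not found in {path.name}; "
                            f"file has {list(df.columns)}")

    if time_column is not None and time_column in df.columns:
        t = pd.to_numeric(df[time_column], errors="coerce").to_numpy(float)
        dt = np.nanmedian(np.diff(t))
        if not np.isfinite(dt) or abs(dt - 1.0 / fs) > 0.01 / fs:
            raise SignalIOError(
                f"time column increment {dt:.6g} s inconsistent with fs={fs} Hz")

    cols = {file_col: pd.to_numeric(df[file_col], errors="coerce")
            for file_col in column_map}
    data = pd.DataFrame(cols)
    keep = np.isfinite(data.to_numpy(float)).all(axis=1)
    if not keep.all():
        logger.warning("%s: dropped %d row(s) with non-finite values",
                       path.name, int((~keep).sum()))
    data = data.loc[keep]

    channels = {chan: data[file_col].to_numpy(float)
                for file_col, chan in column_map.items()}
    return NirsRecording(
        participant_id=participant_id or path.stem,
        fs=fs,
        channels=channels,
    )


def write_nirs_csv(rec: NirsRecording, path: str | Path) -> Path:
    """Write a recording as CSV with a ``time_s`` column and one column per
    channel. Round-trips through :func:`read_nirs_csv` to 1e-9."""
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.time()})
    for name in KNOWN_CHANNELS:
        if name in rec.channels:
            df[name] = rec.channels[name]
    for name in rec.channels:  # any non-standard channels last
        if name not in df.columns:
            df[name] = rec.channels[name]
    df.to_csv(path, index=False, float_format="%.10f")
    return path


def segment_by_protocol(
    rec: NirsRecording, sched: ProtocolSchedule
) -> list[ConditionSegment]:
    """Slice a recording into the scheduled conditions.

    Segment ``k`` spans samples ``[round(Σ_{j<k} d_j·fs), round(Σ_{j<=k} d_j·fs))``
    (half-open), so the segments partition the scheduled span with no gaps or
    overlaps even when duration × fs is not an integer.
    """
    durations = np.array([d for _, d in sched.stages], dtype=float)
    boundaries = np.rint(np.cumsum(np.concatenate([[0.0], durations])) * rec.fs)
    boundaries = boundaries.astype(int)
    if boundaries[-1] > rec.n_samples:
        raise SignalIOError(
            f"recording ({rec.n_samples} samples) shorter than schedule "
            f"({boundaries[-1]} samples needed)")
    segments = []
    for (name, _), lo, hi in zip(sched.stages, boundaries[:-1], boundaries[1:]):
        segments.append(ConditionSegment(
            condition_name=name,
            start_index=int(lo),
            end_index=int(hi),
            channels={c: v[lo:hi] for c, v in rec.channels.items()},
            fs=rec.fs,
        ))
    return segments


def write_feature_matrix(fm: pd.DataFrame, path: str | Path) -> Path:
    """Write a window feature matrix as CSV (header + one line per window)."""
    if len(fm) == 0:
        raise SignalIOError("refusing to write an empty feature matrix")
    missing = [c for c in FEATURE_MATRIX_COLUMNS if c not in fm.columns]
    if missing:
        raise SignalIOError(f"feature matrix missing columns {missing}")
    path = Path(path)
    fm.loc[:, FEATURE_MATRIX_COLUMNS].to_csv(path, index=False,
                                             float_format="%.10f")
    return path


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise SignalIOError(f"feature matrix missing columns {missing}")
    return df
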