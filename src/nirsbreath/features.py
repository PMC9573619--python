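"""Per-breath and per-window respiratory features.

One breath is the span between two consecutive respiratory minima of the
detrended O₂Hb signal. Per breath:

* breathing interval — time between the two minima (s);
* breathing depth — O₂Hb difference between the intervening maximum and the
  starting minimum (μM).

Breaths whose interval falls outside the participant-and-condition tolerance
band mean ± z·SD (z = 1.96 at the default 95% level) are excluded together
with their depths. Surviving breaths are aggregated into non-overlapping
1-minute windows, alongside the window's mean raw ΔO₂Hb level (the "O₂Hb
signal amplitude" feature).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .breath_detection import PeakSet
from .signal_io import ConditionSegment

logger = logging.getLogger("nirsbreath")

DEFAULT_CI_LEVEL = 0.95
DEFAULT_WINDOW_S = 60.0

BREATH_TABLE_COLUMNS = (
    "min_index_start", "max_index", "min_index_end",
    "interval_s", "depth", "excluded",
)


def _empty_breath_table() -> pd.DataFrame:
    return pd.DataFrame({
        "min_index_start": pd.Series(dtype=int),
        "max_index": pd.Series(dtype=int),
        "min_index_end": pd.Series(dtype=int),
        "interval_s": pd.Series(dtype=float),
        "depth": pd.Series(dtype=float),
        "excluded": pd.Series(dtype=bool),
    })


def compute_breath_features(
    peaks: PeakSet, signal: np.ndarray, fs: float
) -> pd.DataFrame:
    """Build the per-breath table from an alternating peak set.

    One row per consecutive-minima pair: interval_s is the minima time
    difference, depth the signal difference between the unique intervening
    maximum and the starting minimum. Requires an alternating PeakSet; with
    fewer than two minima an empty table is returned with a warning.
    """
    if not peaks.alternating:
        raise ValueError("compute_breath_features requires an alternating PeakSet")
    x = np.asarray(signal, dtype=float)
    minima = peaks.minima
    if len(minima) < 2:
        logger.warning("fewer than 2 minima: empty breath table")
        return _empty_breath_table()
    rows = []
    for lo, hi in zip(minima[:-1], minima[1:]):
        between = peaks.maxima[(peaks.maxima > lo) & (peaks.maxima < hi)]
        if len(between) != 1:  # cannot happen for an alternating set
            raise ValueError(
                f"expected exactly one maximum in ({lo}, {hi}), got {len(between)}")
        mx = int(between[0])
        rows.append((int(lo), mx, int(hi),
                     (hi - lo) / fs, x[mx] - x[lo], False))
    return pd.DataFrame(rows, columns=list(BREATH_TABLE_COLUMNS))


def filter_outliers_ci(bt: pd.DataFrame, level: float = DEFAULT_CI_LEVEL) -> pd.DataFrame:
    """Flag breaths whose interval falls outside mean ± z·SD of the table.

    The mean and sample SD (n−1 denominator) are computed once over the whole
    table (single pass, not iterated); z is the two-sided normal quantile for
    ``level`` (1.96 at 0.95). An excluded breath drops both its interval and
    its depth from downstream averages. With SD = 0 nothing is excluded;
    tables with fewer than 3 rows are returned unchanged with a warning.
    """
    out = bt.copy()
    if len(bt) < 3:
        logger.warning("breath table with %d row(s): CI filter skipped", len(bt))
        return out
    z = stats.norm.ppf(0.5 + level / 2.0)
    iv = bt["interval_s"].to_numpy(float)
    mean, sd = iv.mean(), iv.std(ddof=1)
    if sd == 0:
        return out
    out["excluded"] = np.abs(iv - mean) > z * sd
    return out


def compute_o2hb_amplitude(
    raw_segment: np.ndarray, fs: float, window: tuple[int, int]
) -> float:
    """Mean raw ΔO₂Hb level over a half-open sample window (μM).

    Uses the non-detrended signal: the condition-dependent level shift of
    ΔO₂Hb is the amplitude information that detrending would destroy.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window ({lo}, {hi})")
    x = np.asarray(raw_segment, dtype=float)
    if lo < 0 or hi > len(x):
        raise ValueError(f"window ({lo}, {hi}) outside segment of length {len(x)}")
    return float(x[lo:hi].mean())


def window_aggregate(
    bt: pd.DataFrame,
    segment: ConditionSegment,
    raw_segment: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    participant_id: str = "",
    label: str | None = None,
    amplitude_mode: str = "raw_mean",
) -> pd.DataFrame:
    """Aggregate a filtered breath table into 1-minute window feature rows.

    The segment is cut into ``floor(duration / window_s)`` non-overlapping
    windows (a partial trailing window is dropped). A breath belongs to the
    window containing its starting minimum. Per window: the mean interval and
    mean depth over non-excluded breaths, and the O₂Hb amplitude. Windows
    with zero surviving breaths are dropped with a warning.

    ``amplitude_mode`` selects the amplitude definition: ``raw_mean`` (the
    window mean of the raw ΔO₂Hb level, default) or ``oscillation`` (mean
    per-breath peak-to-trough on the raw signal, for sensitivity analysis).

    ``label`` is the class label column (defaults to the condition name);
    pass ``""`` to mask a condition out of classification.
    """
    raw = np.asarray(raw_segment, dtype=float)
    n_windows = int(len(raw) / fs // window_s)
    if n_windows == 0:
        raise ValueError(
            f"segment of {len(raw) / fs:.1f} s shorter than one "
            f"{window_s:.0f}-s window")
    if amplitude_mode not in ("raw_mean", "oscillation"):
        raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
    if label is None:
        label = segment.condition_name

    kept = bt.loc[~bt["excluded"]]
    rows = []
    for w in range(n_windows):
        lo = int(round(w * window_s * fs))
        hi = int(round((w + 1) * window_s * fs))
        in_win = kept.loc[(kept["min_index_start"] >= lo)
                          & (kept["min_index_start"] < hi)]
        if len(in_win) == 0:
            logger.warning("%s/%s window %d: no surviving breaths, dropped",
                           participant_id, segment.condition_name, w)
            continue
        if amplitude_mode == "raw_mean":
            amp = compute_o2hb_amplitude(raw, fs, (lo, hi))
        else:
            amp = float((raw[in_win["max_index"].to_numpy(int)]
                         - raw[in_win["min_index_start"].to_numpy(int)]).mean())
        rows.append({
            "participant": participant_id,
            "condition": segment.condition_name,
            "window_index": w,
            "interval_mean_s": float(in_win["interval_s"].mean()),
            "depth_mean": float(in_win["depth"].mean()),
            "o2hb_amplitude": amp,
            "label": label,
        })
    return pd.DataFrame(rows)
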