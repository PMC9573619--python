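"""Respiratory extremum detection on detrended O₂Hb with an alternation constraint.

The procedure has four steps:

1. The ~1 Hz cardiac pulsation riding on the respiratory wave is suppressed
   with a zero-phase low-pass (cutoff above the respiratory band, below the
   cardiac band); all extremum searches run on this working signal.
2. A first-pass extremum search estimates the average spacing between
   consecutive peaks. A prominence floor (a fraction of the segment's
   standard deviation) keeps residual ripple and noise wiggles from being
   counted as breaths.
3. The average spacing, scaled by a safety multiplier, is passed as the
   minimum peak separation to a second peak search: maxima on the signal,
   minima on the inverted signal.
4. Consecutive same-type extrema without the opposite type in between are
   reduced to the single most extreme member, so minima and maxima strictly
   alternate — the prerequisite for defining one breath per minima pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

#: Fraction of the working segment's SD used as the prominence floor.
DEFAULT_PROMINENCE_SD_FRACTION = 0.25

#: The estimated average spacing is multiplied by this before use as the
#: minimum separation, so within-condition rate variability does not
#: suppress true breaths.
DEFAULT_SPACING_MULTIPLIER = 0.5

#: Low-pass cutoff (Hz) separating respiration (≤ ~0.5 Hz) from cardiac
#: pulsation (~1 Hz); 0 disables the filter.
DEFAULT_CARDIAC_CUTOFF_HZ = 0.8


class InsufficientOscillationError(ValueError):
    """Raised when a segment shows too few extrema to estimate breath spacing."""


@dataclass
class PeakSet:
    """Detected maxima and minima (sample indices, sorted ascending)."""

    maxima: np.ndarray
    minima: np.ndarray
    min_separation_s: float
    alternating: bool = False

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=int)
        self.minima = np.asarray(self.minima, dtype=int)
        for name, idx in (("maxima", self.maxima), ("minima", self.minima)):
            if len(idx) > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{name} indices must be strictly increasing")

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All extrema merged in time order.

        Returns (indices, kinds) where kind +1 marks a maximum and -1 a
        minimum."""
        idx = np.concatenate([self.maxima, self.minima])
        kind = np.concatenate([np.ones(len(self.maxima), dtype=int),
                               -np.ones(len(self.minima), dtype=int)])
        order = np.argsort(idx, kind="stable")
        return idx[order], kind[order]


def suppress_cardiac(
    signal: np.ndarray,
    fs: float,
    cutoff_hz: float = DEFAULT_CARDIAC_CUTOFF_HZ,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass removing the cardiac pulsation.

    Applied forward and backward (``filtfilt``) so extremum positions are
    not delayed. With ``cutoff_hz`` = 0 the signal is returned unchanged.
    """
    if cutoff_hz <= 0:
        return np.asarray(signal, dtype=float)
    b, a = butter(order, cutoff_hz, fs=fs)
    return filtfilt(b, a, np.asarray(signal, dtype=float))


def estimate_peak_spacing(
    signal: np.ndarray,
    fs: float,
    prominence_sd_fraction: float = DEFAULT_PROMINENCE_SD_FRACTION,
) -> float:
    """Mean distance (s) between consecutive peaks from a first-pass search.

    Maxima and minima (on the inverted signal) from the first pass are pooled;
    the mean gap between consecutive same-type extrema is returned. Raises
    :class:`InsufficientOscillationError` if fewer than two first-pass peaks
    are found on either polarity.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 3 * fs:
        raise InsufficientOscillationError(
            f"segment too short for spacing estimation: {len(x)} samples")
    floor = prominence_sd_fraction * np.std(x)
    maxima, _ = find_peaks(x, prominence=floor if floor > 0 else None)
    minima, _ = find_peaks(-x, prominence=floor if floor > 0 else None)
    if len(maxima) < 2 and len(minima) < 2:
        raise InsufficientOscillationError(
            "insufficient oscillation: fewer than 2 first-pass peaks")
    gaps = []
    if len(maxima) >= 2:
        gaps.append(np.diff(maxima))
    if len(minima) >= 2:
        gaps.append(np.diff(minima))
    spacing = float(np.mean(np.concatenate(gaps))) / fs
    return spacing


def detect_extrema(
    signal: np.ndarray,
    fs: float,
    min_separation_s: float,
    spacing_multiplier: float = DEFAULT_SPACING_MULTIPLIER,
    prominence: float | None = None,
) -> PeakSet:
    """Detect maxima and minima with a minimum mutual separation.

    The separation in samples is ``round(min_separation_s * fs *
    spacing_multiplier)``; among peaks closer than that, the higher-amplitude
    one is kept (minima are found by the same procedure on the negated
    signal). ``prominence`` optionally imposes an absolute prominence floor
    in addition to the separation (used by :func:`detect_breaths` to ignore
    low-amplitude noise wiggles that happen to clear the separation). An
    empty PeakSet is a valid result (e.g. a flat signal).
    """
    if min_separation_s <= 0:
        raise ValueError(f"min_separation_s must be > 0, got {min_separation_s}")
    x = np.asarray(signal, dtype=float)
    distance = max(1, int(round(min_separation_s * fs * spacing_multiplier)))
    maxima, _ = find_peaks(x, distance=distance, prominence=prominence)
    minima, _ = find_peaks(-x, distance=distance, prominence=prominence)
    return PeakSet(maxima=maxima, minima=minima,
                   min_separation_s=min_separation_s)


def enforce_alternation(peaks: PeakSet, signal: np.ndarray) -> PeakSet:
    """Reduce runs of consecutive same-type extrema to their most extreme member.

    After this step the time-merged extremum sequence strictly alternates
    between minima and maxima. Idempotent on already-alternating input.
    """
    x = np.asarray(signal, dtype=float)
    idx, kind = peaks.merged()
    keep_max: list[int] = []
    keep_min: list[int] = []
    i = 0
    while i < len(idx):
        j = i
        while j + 1 < len(idx) and kind[j + 1] == kind[i]:
            j += 1
        run = idx[i:j + 1]
        if kind[i] > 0:
            keep_max.append(int(run[np.argmax(x[run])]))
        else:
            keep_min.append(int(run[np.argmin(x[run])]))
        i = j + 1
    return PeakSet(maxima=np.array(keep_max, dtype=int),
                   minima=np.array(keep_min, dtype=int),
                   min_separation_s=peaks.min_separation_s,
                   alternating=True)


def detect_breaths(
    signal: np.ndarray,
    fs: float,
    spacing_multiplier: float = DEFAULT_SPACING_MULTIPLIER,
    prominence_sd_fraction: float = DEFAULT_PROMINENCE_SD_FRACTION,
    cardiac_cutoff_hz: float = DEFAULT_CARDIAC_CUTOFF_HZ,
) -> PeakSet:
    """Full respiratory extremum detection on a detrended segment.

    Composes cardiac suppression, spacing estimation, separation-constrained
    extremum detection, and alternation enforcement. Returned indices locate
    extrema of the cardiac-suppressed working signal (obtain it with
    :func:`suppress_cardiac` to read amplitudes at those indices).
    Propagates :class:`InsufficientOscillationError` from the first pass.
    """
    x = suppress_cardiac(signal, fs, cardiac_cutoff_hz)
    spacing = estimate_peak_spacing(x, fs, prominence_sd_fraction)
    floor = prominence_sd_fraction * float(np.std(x))
    raw = detect_extrema(x, fs, spacing, spacing_multiplier,
                         prominence=floor if floor > 0 else None)
    return enforce_alternation(raw, x)
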