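"""Polynomial detrending of O₂Hb segments prior to peak detection.

Chest-optode O₂Hb traces carry large slow trends (posture, perfusion,
instrument drift) on top of the respiratory oscillation. A 6th-order
least-squares polynomial in time is fitted and subtracted; the respiratory
band (~0.2–0.5 Hz over minutes-long segments) is far above anything a
6th-order polynomial can follow, so breaths pass through unattenuated.
Detrending is applied per condition segment, not to the whole record, so a
trend in one condition cannot leak into another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_DETREND_ORDER = 6


@dataclass
class DetrendResult:
    """Detrended signal, the fitted trend, and the polynomial order used.

    Invariant: ``detrended + trend == input`` elementwise (to 1e-9).
    """

    detrended: np.ndarray
    trend: np.ndarray
    order: int


def detrend_polynomial(
    signal: np.ndarray, fs: float | None = None, order: int = DEFAULT_DETREND_ORDER
) -> DetrendResult:
    """Fit and subtract a least-squares polynomial of the given order.

    The fit uses a time axis mapped to [-1, 1] for numerical conditioning
    (a 6th-order Vandermonde system in raw seconds is badly conditioned over
    minutes-long segments). ``fs`` only fixes the time axis scale and does
    not affect the result; it may be omitted.

    Raises
    ------
    ValueError
        If the signal is shorter than ``order + 2`` samples or non-finite.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {x.shape}")
    if len(x) < order + 2:
        raise ValueError(
            f"signal too short for order-{order} detrend: {len(x)} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    t = np.arange(len(x), dtype=float)
    if fs is not None:
        t /= fs
    # Polynomial.fit maps the domain to [-1, 1] internally.
    poly = np.polynomial.Polynomial.fit(t, x, deg=order)
    trend = poly(t)
    return DetrendResult(detrended=x - trend, trend=trend, order=order)
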