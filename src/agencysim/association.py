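"""Correlation between prediction errors and self-other judgments.

The central analysis: over the FAKE trials of a session, the Pearson
correlation between each trial's mean pen-cursor distance and its 9-point
self-other judgment, with a two-tailed p-value from the t transform

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   df = n - 2

and a conventional magnitude label on |r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError

__all__ = [
    "MAGNITUDE_BOUNDS",
    "CorrelationResult",
    "pearson_r",
    "r_p_value",
    "classify_magnitude",
    "correlate",
]

#: |r| bin edges for the low / moderate / high / very-high labels (closed-open bins).
MAGNITUDE_BOUNDS: tuple[float, float, float] = (0.5, 0.7, 0.9)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float
    magnitude_label: str
    saturated: bool = False  # |r| == 1; p reported as 0


def pearson_r(xs, ys) -> float:
    """Pearson product-moment correlation coefficient.

    Raises :class:`DegenerateVarianceError` when either input is constant
    rather than silently returning 0 or NaN.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be 1-d and of equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateVarianceError("correlation undefined for a constant input")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return max(-1.0, min(1.0, r))


def r_p_value(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson r at sample size n via the t transform."""
    if n < 3:
        raise ValueError("p-value undefined for n < 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0  # saturated; flagged by correlate()
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def classify_magnitude(r: float, bounds: tuple[float, float, float] = MAGNITUDE_BOUNDS) -> str:
    """Label |r| as low / moderate / high / very high (closed-open bins)."""
    a = abs(r)
    if a > 1:
        raise ValueError("|r| must be <= 1")
    lo, mid, hi = bounds
    if a < lo:
        return "low"
    if a < mid:
        return "moderate"
    if a < hi:
        return "high"
    return "very high"


def correlate(xs, ys, bounds: tuple[float, float, float] = MAGNITUDE_BOUNDS) -> CorrelationResult:
    """Full correlation analysis of one session's FAKE trials."""
    r = pearson_r(xs, ys)
    n = int(np.asarray(xs).size)
    saturated = abs(r) == 1.0
    return CorrelationResult(r, n, r_p_value(r, n), classify_magnitude(r, bounds), saturated)
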