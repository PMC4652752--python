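"""Doubling-time estimation from viable-count (CFU/ml) growth curves.

A log-linear fit over a user-chosen exponential window: ordinary least
squares of log2(CFU) against time, doubling time = 1/slope.  The default
window of 60–180 min after dilution into fresh medium is where batch LB
cultures are reliably exponential.  Window selection itself is left to the
analyst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_data import GrowthCurve

DEFAULT_WINDOW_MIN = (60.0, 180.0)


class NoGrowthError(ValueError):
    """Raised when the fitted slope is nonpositive (no exponential growth)."""


@dataclass(frozen=True)
class DoublingTimeEstimate:
    doubling_time_min: float
    window_used: tuple[float, float]
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "doubling_time_min": self.doubling_time_min,
            "window_used_min": list(self.window_used),
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def fit_doubling_time(
    curve: GrowthCurve,
    window: tuple[float, float] = DEFAULT_WINDOW_MIN,
) -> DoublingTimeEstimate:
    """OLS of log2(CFU/ml) vs time (min) over ``window``; doubling time = 1/slope.

    The estimate is exactly invariant to rescaling the counts.  Zero or
    negative counts inside the window invalidate the fit rather than being
    dropped silently.
    """
    t0, t1 = window
    times = np.asarray(curve.times_min, dtype=float)
    cfu = np.asarray(curve.cfu_per_ml, dtype=float)
    sel = (times >= t0) & (times <= t1)
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 points in window {window}, found {int(sel.sum())}")
    if np.any(cfu[sel] <= 0):
        raise ValueError("nonpositive CFU count inside the fitting window")
    res = stats.linregress(times[sel], np.log2(cfu[sel]))
    if res.slope <= 0:
        raise NoGrowthError(f"nonpositive growth slope {res.slope:.3g}/min")
    return DoublingTimeEstimate(
        doubling_time_min=float(1.0 / res.slope),
        window_used=(float(t0), float(t1)),
        r_squared=float(res.rvalue**2),
        n_points=int(sel.sum()),
    )
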