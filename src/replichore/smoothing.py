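"""Locally weighted quadratic regression (LOESS) on a circular genome.

The smoother fits, at every bin centre, a degree-2 polynomial by weighted
least squares to the ``q = round(frac * n)`` nearest unmasked points, with
tricube weights on *circular* distance and local coordinates re-centred at
the evaluation point so the fit is continuous across the origin of the
coordinate system (periodic boundary conditions).  The default fraction of
0.10 on a 1-kb-binned 4.64 Mbp genome corresponds to a smoothing window of
around 460 kbp.

Outlier handling follows the squared-residual rule: points with
``(enrichment - fitted)^2`` above the threshold (default 0.02) are dropped
and the curve refit on the retained points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .mfa import MarkerFrequencyProfile


@dataclass
class SmoothingParams:
    frac: float = 0.10
    degree: int = 2
    outlier_threshold: float = 0.02
    refit_passes: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.frac <= 1:
            raise ValueError("frac must be in (0, 1]")
        if self.degree not in (1, 2):
            raise ValueError("local polynomial degree must be 1 or 2")
        if self.outlier_threshold <= 0:
            raise ValueError("outlier threshold must be positive")
        if self.refit_passes < 0:
            raise ValueError("refit_passes must be nonnegative")

    def n_neighbours(self, n_points: int) -> int:
        q = int(round(self.frac * n_points))
        return max(q, self.degree + 1)

    def window_bp(self, n_points: int, bin_width_bp: int) -> int:
        """Nominal smoothing window: q bins of data."""
        return self.n_neighbours(n_points) * bin_width_bp

    def reported_window_kbp(self, n_points: int, bin_width_bp: int) -> int:
        """The window as quoted in reports, rounded to the nearest 10 kbp."""
        kbp = Decimal(self.window_bp(n_points, bin_width_bp)) / Decimal(1000)
        return int((kbp / 10).quantize(Decimal(1), rounding=ROUND_HALF_UP) * 10)


@dataclass
class SmoothedProfile:
    """LOESS fit evaluated at every bin, plus the retained-point mask.

    ``fitted`` is defined at every bin, including masked or removed ones —
    exclusion affects fitting, not evaluation.  ``retained`` is True for
    bins that were unmasked and survived outlier removal.
    """

    fitted: np.ndarray
    retained: np.ndarray
    params: SmoothingParams
    bin_width_bp: int
    genome_length_bp: int

    def __post_init__(self) -> None:
        self.fitted = np.asarray(self.fitted, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.fitted)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_bp


def tricube_weight(d, d_max: float):
    """Tricube kernel ``(1 - (d/d_max)^3)^3`` for ``d < d_max``, else 0."""
    if d_max <= 0:
        raise ValueError("window radius must be positive")
    u = np.clip(np.abs(np.asarray(d, dtype=float)) / d_max, 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _circular_windows(eval_pos: np.ndarray, sample_pos: np.ndarray, L: float, q: int):
    """Index windows of the q circularly nearest sample points per eval point.

    Ties at the q-th nearest distance are all included, so the selection is
    deterministic and symmetric.  Returns (starts, lengths) into the tripled
    sample array ``[P - L, P, P + L]``.
    """
    m = len(sample_pos)
    q = min(q, m)
    p3 = np.concatenate([sample_pos - L, sample_pos, sample_pos + L])
    n3 = 3 * m
    eval_pos = np.asarray(eval_pos, dtype=float)
    starts = np.empty(len(eval_pos), dtype=np.int64)
    lengths = np.empty(len(eval_pos), dtype=np.int64)
    lo = hi = -1
    for k, x in enumerate(eval_pos):
        if lo < 0:
            lo = hi = int(np.searchsorted(p3, x))
            while hi - lo < q:  # greedy q-nearest: always a contiguous window
                left = x - p3[lo - 1] if lo > 0 else np.inf
                right = p3[hi] - x if hi < n3 else np.inf
                if left <= right:
                    lo -= 1
                else:
                    hi += 1
        else:
            # eval points ascend, so the optimal window only shifts right
            while hi < n3 and (x - p3[lo]) > (p3[hi] - x):
                lo += 1
                hi += 1
        d_max = max(x - p3[lo], p3[hi - 1] - x)
        # include all points tied with the q-th nearest distance
        tlo, thi = lo, hi
        while tlo > 0 and x - p3[tlo - 1] <= d_max + 1e-9:
            tlo -= 1
        while thi < n3 and p3[thi] - x <= d_max + 1e-9:
            thi += 1
        starts[k] = tlo
        lengths[k] = thi - tlo
    return starts, lengths


def _loess_fit(
    eval_pos: np.ndarray,
    sample_pos: np.ndarray,
    y: np.ndarray,
    L: float,
    q: int,
    degree: int = 2,
) -> np.ndarray:
    """Periodic LOESS core: fitted values at ``eval_pos``.

    Batched over evaluation points: windows are padded to a common width
    with zero weights and the per-point (degree+1) x (degree+1) normal
    equations solved in one vectorised call.
    """
    m = len(sample_pos)
    if q < degree + 1:
        raise ValueError(f"q = {q} too small to fit a degree-{degree} polynomial")
    if m < degree + 1:
        raise ValueError("not enough sample points")
    p3 = np.concatenate([sample_pos - L, sample_pos, sample_pos + L])
    y3 = np.concatenate([y, y, y])
    starts, lengths = _circular_windows(eval_pos, sample_pos, L, q)
    wmax = int(lengths.max())
    idx = starts[:, None] + np.arange(wmax)[None, :]
    pad = np.arange(wmax)[None, :] >= lengths[:, None]
    idx = np.minimum(idx, 3 * m - 1)

    u = p3[idx] - np.asarray(eval_pos, dtype=float)[:, None]  # local coords
    u[pad] = 0.0
    d_max = np.abs(u).max(axis=1, keepdims=True)
    d_max = np.maximum(d_max, 1e-12)
    w = (1.0 - np.clip(np.abs(u) / d_max, 0.0, 1.0) ** 3) ** 3
    w[pad] = 0.0
    us = u / d_max  # scaled to [-1, 1] for conditioning

    cols = [np.ones_like(us), us, us**2][: degree + 1]
    X = np.stack(cols, axis=-1)  # (n, wmax, p)
    yw = y3[idx]
    A = np.einsum("nwp,nw,nwq->npq", X, w, X)
    b = np.einsum("nwp,nw,nw->np", X, w, yw)
    # guard against exactly singular windows (all weight on one abscissa)
    A += 1e-12 * np.eye(degree + 1)[None, :, :]
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    return beta[:, 0]  # value of the local polynomial at u = 0


def _as_profile_arrays(y) -> tuple[np.ndarray, np.ndarray, int, int]:
    if isinstance(y, MarkerFrequencyProfile):
        return y.enrichment, y.mask, y.bin_width_bp, y.genome_length_bp
    arr = np.asarray(y, dtype=float)
    mask = ~np.isfinite(arr)
    return arr, mask, 1, len(arr)


def loess_periodic(y, params: SmoothingParams | None = None) -> SmoothedProfile:
    """Periodic LOESS of a marker-frequency profile (or plain circular array).

    Masked bins are excluded from the fit but still receive fitted values.
    """
    params = params or SmoothingParams()
    values, mask, bw, L = _as_profile_arrays(y)
    n = len(values)
    keep = ~mask
    if not keep.any():
        raise ValueError("all bins are masked")
    pos = np.arange(n, dtype=float) * bw
    q = params.n_neighbours(int(keep.sum()))
    fitted = _loess_fit(pos, pos[keep], values[keep], float(L), q, params.degree)
    return SmoothedProfile(fitted, keep.copy(), params, bw, L)


def remove_outliers_and_refit(y, params: SmoothingParams | None = None) -> SmoothedProfile:
    """Fit, drop points with squared residual above threshold, refit.

    One removal pass by default; the returned ``retained`` mask marks the
    points that contributed to the final curve.
    """
    params = params or SmoothingParams()
    values, mask, bw, L = _as_profile_arrays(y)
    n = len(values)
    pos = np.arange(n, dtype=float) * bw
    retained = ~mask

    def _fit(mask_now: np.ndarray) -> np.ndarray:
        if mask_now.sum() < params.degree + 1:
            raise ValueError("outlier removal left too few points to fit")
        q = params.n_neighbours(int(mask_now.sum()))
        return _loess_fit(pos, pos[mask_now], values[mask_now], float(L), q, params.degree)

    fitted = _fit(retained)
    for _ in range(params.refit_passes):
        bad = retained & ((values - fitted) ** 2 > params.outlier_threshold)
        if not bad.any():
            break
        retained = retained & ~bad
        fitted = _fit(retained)
    return SmoothedProfile(fitted, retained, params, bw, L)
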