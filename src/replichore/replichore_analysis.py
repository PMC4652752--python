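"""Terminus minima, replichore asymmetry and rrn gradient-deviation scores.

The smoothed marker-frequency curve has one minimum per inter-origin arc:
the point where the two converging forks meet on a population basis.  For
one origin this is the global minimum of the curve; for two origins the
circle is split at the origins and each open arc searched separately.
Minima are compared with the arithmetic midpoints between origins, signed
shifts and per-origin replichore lengths derived, and highly transcribed
regions scored for locally steepened gradients (a signature of
replication–transcription conflict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromosome import (
    ChromosomeConfig,
    Midpoint,
    arc_length_cw,
    format_mbp,
    in_arc_cw,
    signed_arc_offset,
)
from .smoothing import SmoothedProfile

GRADIENT_EPS = 1e-6  # minimal per-bin |log2 slope| for a defined score


class FlatArmError(ValueError):
    """Raised when a replichore arm is too flat to define a gradient baseline."""


@dataclass(frozen=True)
class TerminationMinimum:
    """Fitted-curve minimum within one inter-origin arc."""

    arc_from: str
    arc_to: str
    position_bp: int
    value: float
    suspect: bool = False  # minimum sits on the arc boundary

    @property
    def position_mbp(self) -> float:
        return format_mbp(self.position_bp, 3)


@dataclass
class ReplichoreReport:
    """Machine-readable summary: minima, midpoints, shifts, arm lengths, scores."""

    minima: list[TerminationMinimum]
    midpoints: list[Midpoint]
    shifts_kb: list[float]
    replichore_lengths_mbp: dict[str, dict[str, float]]
    deviation_scores: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "minima": [
                {"arc": [m.arc_from, m.arc_to], "position_mbp": m.position_mbp,
                 "value": m.value, "suspect": m.suspect}
                for m in self.minima
            ],
            "midpoints": [
                {"arc": [m.arc_from, m.arc_to], "position_mbp": m.position_mbp}
                for m in self.midpoints
            ],
            "shifts_kb": self.shifts_kb,
            "replichore_lengths_mbp": self.replichore_lengths_mbp,
            "deviation_scores": self.deviation_scores,
        }


def find_termination_minima(
    s: SmoothedProfile, config: ChromosomeConfig
) -> list[TerminationMinimum]:
    """Minimum of the fitted curve in each open inter-origin arc.

    Arcs are open at the origins, so an origin bin can never be reported as
    a terminus.  Ties are broken toward the smaller genomic coordinate; a
    minimum on an arc-boundary bin is flagged as suspect.
    """
    if not 1 <= len(config.origins) <= 2:
        raise ValueError("minima search supports 1 or 2 origins")
    L = config.length_bp
    w = s.bin_width_bp
    pos = s.bin_starts
    origins = sorted(config.origins, key=lambda o: o.position_bp)
    k = len(origins)
    out = []
    for i in range(k):
        a, b = origins[i], origins[(i + 1) % k]
        off = (pos - a.position_bp) % L
        D = (b.position_bp - a.position_bp) % L or L
        # open arc: exclude any bin containing an origin
        contains_origin = np.zeros_like(pos, dtype=bool)
        for o in origins:
            contains_origin |= (o.position_bp - pos) % L < w
        in_open = (off < D) & ~contains_origin
        idx = np.flatnonzero(in_open)
        if idx.size == 0:
            raise ValueError(f"arc {a.name}->{b.name} contains no bins")
        vals = s.fitted[idx]
        best = idx[np.lexsort((pos[idx], vals))[0]]
        # boundary flag: first/last bin of the arc in clockwise order
        order = idx[np.argsort((pos[idx] - a.position_bp) % L)]
        suspect = best in (order[0], order[-1])
        out.append(
            TerminationMinimum(a.name, b.name, int(pos[best]), float(s.fitted[best]), suspect)
        )
    return out


def replichore_report(
    minima: list[TerminationMinimum],
    config: ChromosomeConfig,
    deviation_scores: dict[str, float] | None = None,
) -> ReplichoreReport:
    """Midpoint comparison and per-origin replichore lengths.

    Shifts are the signed clockwise offset from the arithmetic midpoint to
    the fitted minimum of the same arc, in kb (positive = minimum clockwise
    of the midpoint).  Replichore lengths are the clockwise and
    counterclockwise arc lengths from each origin to the adjacent minima.
    """
    L = config.length_bp
    midpoints = config.midpoints()
    by_arc = {(m.arc_from, m.arc_to): m for m in midpoints}
    shifts = []
    for m in minima:
        mid = by_arc.get((m.arc_from, m.arc_to))
        if mid is None:
            raise ValueError(f"no midpoint for arc {m.arc_from}->{m.arc_to}")
        shifts.append(signed_arc_offset(mid.position_bp % L, m.position_bp, L) / 1000.0)

    lengths: dict[str, dict[str, float]] = {}
    min_by_start = {m.arc_from: m for m in minima}
    min_by_end = {m.arc_to: m for m in minima}
    for o in config.origins:
        cw_min = min_by_start[o.name]
        ccw_min = min_by_end[o.name]
        cw_len = arc_length_cw(o.position_bp, cw_min.position_bp, L)
        ccw_len = arc_length_cw(ccw_min.position_bp, o.position_bp, L)
        lengths[o.name] = {
            "clockwise": format_mbp(cw_len, 3),
            "counterclockwise": format_mbp(ccw_len, 3),
        }
    return ReplichoreReport(minima, midpoints, shifts, lengths, deviation_scores or {})


def _log2_gradient(fitted: np.ndarray) -> np.ndarray:
    """Central-difference gradient of log2(fitted), per bin, circular."""
    lf = np.log2(np.clip(fitted, 1e-300, None))
    return (np.roll(lf, -1) - np.roll(lf, 1)) / 2.0


def gradient_deviation_scores(
    s: SmoothedProfile,
    regions,
    config: ChromosomeConfig,
    minima: list[TerminationMinimum],
) -> dict[str, float]:
    """Ratio of a region's mean |log2 gradient| to its arm's baseline median.

    The baseline is the median per-bin |log2 gradient| over the replichore
    arm that contains the region, excluding every annotated slow zone and
    every query region, so conflict zones do not contaminate their own
    reference.  A score above 1 means the profile is locally steeper than
    its arm — the expected signature of a head-on conflict region.  Scores
    are invariant to rescaling the profile.
    """
    L = config.length_bp
    pos = s.bin_starts
    g = np.abs(_log2_gradient(s.fitted))

    # arms: origin -> adjacent minimum, both ways around
    arms: list[tuple[float, float]] = []
    for m in minima:
        a = config.origin(m.arc_from).position_bp
        b = config.origin(m.arc_to).position_bp
        arms.append((a, m.position_bp))
        arms.append((m.position_bp, b))

    excluded = np.zeros(s.n_bins, dtype=bool)
    all_regions = list(regions) + list(config.slow_zones)
    for z in all_regions:
        excluded |= np.array([in_arc_cw(p, z.start_bp, z.end_bp, L) for p in pos])

    scores: dict[str, float] = {}
    for z in regions:
        in_region = np.array([in_arc_cw(p, z.start_bp, z.end_bp, L) for p in pos])
        if not in_region.any():
            raise ValueError(f"region {z.name} covers no bins")
        arm = None
        centre = (z.start_bp + z.length_bp(L) / 2) % L
        for a, b in arms:
            if in_arc_cw(centre, a, b, L):
                arm = (a, b)
                break
        if arm is None:
            raise ValueError(f"region {z.name} lies in no replichore arm")
        in_arm = np.array([in_arc_cw(p, arm[0], arm[1], L) for p in pos])
        base_bins = in_arm & ~excluded
        if not base_bins.any():
            raise FlatArmError(f"no baseline bins left in the arm of {z.name}")
        baseline = float(np.median(g[base_bins]))
        if baseline < GRADIENT_EPS:
            raise FlatArmError(
                f"arm of region {z.name} is flat (median |log2 gradient| "
                f"{baseline:.2e} < {GRADIENT_EPS}); score undefined"
            )
        scores[z.name] = float(np.mean(g[in_region]) / baseline)
    return scores
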