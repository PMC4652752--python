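"""Forward simulator of replication-fork kinetics on a circular chromosome.

The model: every configured origin fires once, simultaneously, at t = 0 and
launches one clockwise and one counterclockwise fork.  Forks travel at a
constant speed (default 1000 bp/s), locally rescaled inside highly
transcribed slow zones — head-on encounters with transcription slow a fork
to ``head_on_factor`` of full speed, co-directional passage to
``codirectional_factor``.  A fork reaching a polar ter site whose polarity
opposes it arrests there (with the site's efficiency) and waits until the
converging fork arrives; the two then fuse at the trap.  Barrier elements
impose a fixed pause.  The output is the time at which every bin is
replicated, from which steady-state relative copy numbers, sequencing count
pairs, rearranged tracks and viable-count growth curves are derived.

Copy number follows the steady-state exponential-population law
``M(x) = 2^(-t_rep(x) / tau_d)`` with ``tau_d`` the culture doubling time:
in a population of exponentially growing cells the abundance of a locus
replicated a time t after initiation is diluted by the cells born in
between.  This is the minimal model producing the observed origin-to-
terminus gradients; a single synchronous initiation round is assumed (no
multifork replication).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chromosome import CLOCKWISE, COUNTERCLOCKWISE, ChromosomeConfig, SlowZone
from .mfa import BinnedCoverage, MarkerFrequencyProfile, DEFAULT_BIN_WIDTH


class UnreachableRegionError(RuntimeError):
    """Raised when opposing traps leave part of the chromosome unreplicated."""


@dataclass
class SimulationParams:
    """Knobs of the forward model.

    fork_speed_bp_per_s : unperturbed fork velocity (default 1000 bp/s).
    doubling_time_min   : culture doubling time; 19.9 min is wild-type-like,
                          39.8 min matches a strain replicating from the
                          ectopic origin only.
    mean_depth_per_bin  : expected sequencing depth per bin in each library.
    bias_sd_log         : sd of the per-bin lognormal mappability bias,
                          drawn once and shared between both libraries.
    noise_model         : "poisson" or "negative_binomial" (with
                          ``nb_dispersion`` as the NB size parameter).
    tus_active          : when False all ter sites are transparent.
    rpo_star            : RNA-polymerase-destabilising mutation; moves every
                          slow-zone speed factor toward 1 by
                          ``rpo_star_relief`` (deficit multiplied by 1-relief).
    """

    fork_speed_bp_per_s: float = 1000.0
    doubling_time_min: float = 19.9
    mean_depth_per_bin: float = 100.0
    bias_sd_log: float = 0.0
    noise_model: str = "poisson"
    nb_dispersion: float = 10.0
    seed: int = 0
    tus_active: bool = True
    rpo_star: bool = False
    rpo_star_relief: float = 0.5
    bin_width_bp: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.fork_speed_bp_per_s <= 0:
            raise ValueError("fork speed must be positive")
        if self.doubling_time_min <= 0:
            raise ValueError("doubling time must be positive")
        if self.mean_depth_per_bin <= 0:
            raise ValueError("mean depth must be positive")
        if self.bias_sd_log < 0:
            raise ValueError("bias_sd_log must be nonnegative")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0 <= self.rpo_star_relief <= 1:
            raise ValueError("rpo_star_relief must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Named deterministic substream of the master seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class ReplicationTiming:
    """Per-bin replication times plus the fork event log."""

    t_rep: np.ndarray
    bin_width_bp: int
    genome_length_bp: int
    termination_positions: list[float]
    events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_rep = np.asarray(self.t_rep, dtype=float)
        if np.any(~np.isfinite(self.t_rep)) or np.any(self.t_rep < 0):
            raise ValueError("t_rep must be finite and nonnegative everywhere")

    @property
    def n_bins(self) -> int:
        return len(self.t_rep)

    @property
    def t_max(self) -> float:
        return float(self.t_rep.max())


@dataclass
class GrowthCurve:
    """Viable-count time series with the generating subpopulation mixture."""

    times_min: np.ndarray
    cfu_per_ml: np.ndarray
    subpopulations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.cfu_per_ml = np.asarray(self.cfu_per_ml, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cfu_per_ml <= 0):
            raise ValueError("cfu counts must be positive")


def _effective_zones(config: ChromosomeConfig, params: SimulationParams) -> list[SlowZone]:
    if not params.rpo_star:
        return list(config.slow_zones)
    keep = 1.0 - params.rpo_star_relief
    return [
        replace(
            z,
            head_on_factor=1.0 - keep * (1.0 - z.head_on_factor),
            codirectional_factor=1.0 - keep * (1.0 - z.codirectional_factor),
        )
        for z in config.slow_zones
    ]


def _dist_along(start: float, pos: float, direction: int, L: float) -> float:
    return (pos - start) % L if direction > 0 else (start - pos) % L


@dataclass
class _ForkProfile:
    """Piecewise-linear free arrival time of one fork along its arc."""

    dists: np.ndarray  # breakpoint distances from the fork's origin
    times: np.ndarray  # arrival times at those distances
    blocked_at: float | None  # arc distance of an arresting ter, if any
    blocked_ter: str | None

    def time_at(self, d: np.ndarray) -> np.ndarray:
        t = np.interp(d, self.dists, self.times)
        if self.blocked_at is not None:
            t = np.where(d > self.blocked_at + 1e-9, np.inf, t)
        return t


def _trace_fork(
    config: ChromosomeConfig,
    zones: list[SlowZone],
    params: SimulationParams,
    start: float,
    direction_sign: int,
    max_dist: float,
    rng: np.random.Generator,
    log: list[dict],
    fork_id: str,
) -> _ForkProfile:
    L = config.length_bp
    direction = CLOCKWISE if direction_sign > 0 else COUNTERCLOCKWISE
    v0 = params.fork_speed_bp_per_s

    # breakpoints: zone boundaries partition the arc into constant-speed
    # segments; ter sites and barriers are point events.
    cuts = {0.0, max_dist}
    for z in zones:
        for p in (z.start_bp, z.end_bp % L):
            d = _dist_along(start, p, direction_sign, L)
            if 0 < d < max_dist:
                cuts.add(d)
    point_events: list[tuple[float, str, object]] = []
    if params.tus_active:
        for t in config.ter_sites:
            if t.blocks(direction):
                d = _dist_along(start, t.position_bp, direction_sign, L)
                if 0 < d < max_dist:
                    point_events.append((d, "ter", t))
                    cuts.add(d)
    for b in config.barriers:
        d = _dist_along(start, b.position_bp, direction_sign, L)
        if 0 < d < max_dist:
            point_events.append((d, "barrier", b))
            cuts.add(d)
    point_events.sort(key=lambda e: e[0])
    grid = np.array(sorted(cuts))

    dists = [0.0]
    times = [0.0]
    blocked_at: float | None = None
    blocked_ter: str | None = None
    pe = 0
    for d0, d1 in zip(grid[:-1], grid[1:]):
        # point events sitting at the start of this segment
        while pe < len(point_events) and point_events[pe][0] <= d0 + 1e-9:
            d, kind, obj = point_events[pe]
            pe += 1
            if kind == "barrier":
                # vertical step: arrival at the barrier is unchanged, all
                # downstream positions are delayed by the pause
                dists.append(d + 1e-6)
                times.append(times[-1] + obj.pause_s)
                log.append({"event": "pause", "fork": fork_id, "element": obj.name,
                            "position_bp": obj.position_bp, "time_s": times[-1]})
            else:  # ter
                arrested = obj.efficiency >= 1.0 or rng.random() < obj.efficiency
                if arrested:
                    blocked_at = d
                    blocked_ter = obj.name
                    log.append({"event": "block", "fork": fork_id, "element": obj.name,
                                "position_bp": obj.position_bp, "time_s": times[-1]})
                    break
        if blocked_at is not None:
            break
        mid = (start + direction_sign * (d0 + d1) / 2) % L
        factor = 1.0
        for z in zones:
            if z.contains(mid, L):
                factor = z.speed_factor(direction)
                break
        dists.append(float(d1))
        times.append(times[-1] + (d1 - d0) / (v0 * factor))
    return _ForkProfile(np.array(dists), np.array(times), blocked_at, blocked_ter)


def _fusion_point(cw: _ForkProfile, ccw: _ForkProfile, D: float) -> tuple[float, float]:
    """Arc coordinate and time at which the two converging forks fuse.

    The clockwise fork covers arc coordinates ``[0, s*]``, the
    counterclockwise fork ``[s*, D]`` (measured clockwise from the arc's
    left origin).
    """
    reach_cw = cw.blocked_at if cw.blocked_at is not None else D
    reach_ccw = D - ccw.blocked_at if ccw.blocked_at is not None else 0.0
    if reach_ccw > reach_cw + 1e-9:
        raise UnreachableRegionError(
            f"region between arc offsets {reach_cw:.0f} and {reach_ccw:.0f} bp "
            "is blocked for both forks"
        )
    # piecewise-linear g(s) = T_cw(s) - T_ccw(D - s) on the overlap
    lo, hi = max(0.0, reach_ccw), min(D, reach_cw)
    s_grid = np.unique(np.concatenate([cw.dists, D - ccw.dists, [lo, hi]]))
    s_grid = s_grid[(s_grid >= lo - 1e-9) & (s_grid <= hi + 1e-9)]
    t_cw = np.interp(s_grid, cw.dists, cw.times)
    t_ccw = np.interp(D - s_grid, ccw.dists, ccw.times)
    g = t_cw - t_ccw
    if g[-1] <= 0:  # clockwise fork wins the whole overlap: it waits at hi
        return hi, float(max(np.interp(hi, cw.dists, cw.times),
                             np.interp(D - hi, ccw.dists, ccw.times)))
    if g[0] >= 0:
        return lo, float(max(np.interp(lo, cw.dists, cw.times),
                             np.interp(D - lo, ccw.dists, ccw.times)))
    k = int(np.searchsorted(g > 0, True))  # first grid point with g > 0
    s0, s1 = s_grid[k - 1], s_grid[k]
    g0, g1 = g[k - 1], g[k]
    s_star = s0 if g1 == g0 else s0 + (0 - g0) * (s1 - s0) / (g1 - g0)
    return float(s_star), float(np.interp(s_star, cw.dists, cw.times))


def simulate_replication_timing(
    config: ChromosomeConfig, params: SimulationParams
) -> ReplicationTiming:
    """Event-driven fork kinetics: per-bin replication times and fusion points.

    Replication time is evaluated at bin-start coordinates, so an origin
    sitting on a bin boundary gives its bin t = 0 exactly.
    """
    if not config.origins:
        raise ValueError("at least one origin is required")
    L = float(config.length_bp)
    w = params.bin_width_bp
    n_bins = -(-config.length_bp // w)
    zones = _effective_zones(config, params)
    rng = params.rng(0)

    origins = sorted(config.origins, key=lambda o: o.position_bp)
    log: list[dict] = [
        {"event": "start", "origin": o.name, "position_bp": o.position_bp, "time_s": 0.0}
        for o in origins
    ]
    t_rep = np.full(n_bins, np.inf)
    fusions: list[float] = []
    bin_starts = np.arange(n_bins, dtype=float) * w

    k = len(origins)
    for i in range(k):
        a = origins[i]
        b = origins[(i + 1) % k]
        D = (b.position_bp - a.position_bp) % L
        if D == 0:
            D = L  # single origin: the arc is the whole circle
        cw = _trace_fork(config, zones, params, a.position_bp, +1, D, rng, log,
                         f"{a.name}:cw")
        ccw = _trace_fork(config, zones, params, b.position_bp, -1, D, rng, log,
                          f"{b.name}:ccw")
        s_star, t_star = _fusion_point(cw, ccw, D)
        fusion_pos = (a.position_bp + s_star) % L
        fusions.append(fusion_pos)
        log.append({"event": "fusion", "position_bp": fusion_pos, "time_s": t_star,
                    "arc": (a.name, b.name)})

        s = (bin_starts - a.position_bp) % L
        in_arc = s < D if k > 1 else np.ones(n_bins, dtype=bool)
        s_arc = s[in_arc]
        t_arc = np.minimum(cw.time_at(s_arc), ccw.time_at(D - s_arc))
        t_rep[in_arc] = np.minimum(t_rep[in_arc], t_arc)

    if np.any(~np.isfinite(t_rep)):
        raise UnreachableRegionError("some bins were never replicated")
    return ReplicationTiming(t_rep, w, config.length_bp, fusions, log)


def timing_to_copy_number(timing: ReplicationTiming, doubling_time_min: float) -> np.ndarray:
    """Noise-free relative copy number ``M = 2^(-t_rep / tau_d)``, origin bins = 1."""
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be positive")
    return np.exp2(-timing.t_rep / (doubling_time_min * 60.0))


def noise_free_profile(
    copy_number: np.ndarray, bin_width_bp: int = DEFAULT_BIN_WIDTH
) -> MarkerFrequencyProfile:
    """Idealised marker-frequency profile: copy number scaled to mean 1.

    This is the expectation of :func:`marker_frequency` applied to counts
    from :func:`sample_count_pair` in the limit of infinite depth.
    """
    m = np.asarray(copy_number, dtype=float)
    return MarkerFrequencyProfile(m / m.mean(), np.zeros(len(m), dtype=bool), bin_width_bp)


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, params: SimulationParams) -> np.ndarray:
    if params.noise_model == "poisson":
        return rng.poisson(lam)
    r = params.nb_dispersion
    return rng.negative_binomial(r, r / (r + lam))


def sample_count_pair(
    copy_number: np.ndarray, params: SimulationParams
) -> tuple[BinnedCoverage, BinnedCoverage]:
    """Sequencing count pair (replicating, stationary control) with shared bias.

    A per-bin lognormal mappability bias is drawn once and applied to both
    libraries; the replicating library's expected depth is additionally
    proportional to the copy number.  Both libraries are scaled to the same
    mean depth so the bias — not library size — is the only shared nuisance.
    """
    m = np.asarray(copy_number, dtype=float)
    n = len(m)
    bias = np.exp(params.rng(1).normal(0.0, params.bias_sd_log, n)) if params.bias_sd_log > 0 \
        else np.ones(n)
    lam_exp = params.mean_depth_per_bin * m * bias / np.mean(m * bias)
    lam_stat = params.mean_depth_per_bin * bias / np.mean(bias)
    exp_counts = _draw_counts(params.rng(2), lam_exp, params)
    stat_counts = _draw_counts(params.rng(3), lam_stat, params)
    w = params.bin_width_bp
    return (
        BinnedCoverage(exp_counts, w, n * w, "exponential"),
        BinnedCoverage(stat_counts, w, n * w, "stationary"),
    )


def apply_inversion(
    track: np.ndarray | BinnedCoverage | MarkerFrequencyProfile,
    b1: int,
    b2: int,
    bin_width_bp: int = DEFAULT_BIN_WIDTH,
    strict: bool = False,
):
    """Reverse the clockwise segment from ``b1`` to ``b2`` of a per-bin track.

    Models a chromosomal inversion at the profile level: the bins covering
    the circular segment ``[b1, b2)`` (clockwise) are written back in
    reverse order.  Applying the same inversion twice restores the input.
    Breakpoints off bin boundaries are snapped (with a warning) unless
    ``strict`` is set.
    """
    if isinstance(track, BinnedCoverage):
        out = apply_inversion(track.counts.copy(), b1, b2, track.bin_width_bp, strict)
        return BinnedCoverage(out, track.bin_width_bp, track.genome_length_bp,
                              track.sample_label)
    if isinstance(track, MarkerFrequencyProfile):
        w = track.bin_width_bp
        enr = apply_inversion(track.enrichment.copy(), b1, b2, w, strict)
        msk = apply_inversion(track.mask.copy(), b1, b2, w, strict)
        return MarkerFrequencyProfile(enr, msk, w, track.genome_length_bp,
                                      sample_label=track.sample_label)

    values = np.asarray(track).copy()
    n = len(values)
    w = bin_width_bp
    if b1 == b2:
        raise ValueError("inversion breakpoints must differ")
    for b in (b1, b2):
        if b % w:
            if strict:
                raise ValueError(f"breakpoint {b} is not on a bin boundary")
            warnings.warn(f"breakpoint {b} snapped to bin boundary", stacklevel=2)
    i1 = (b1 // w) % n
    i2 = (b2 // w) % n
    seg_len = (i2 - i1) % n
    if seg_len == 0:
        return values
    idx = (i1 + np.arange(seg_len)) % n
    values[idx] = values[idx[::-1]]
    return values


def simulate_growth_curve(
    subpopulations: Sequence[tuple[float, float]],
    n0_cfu_per_ml: float = 2e7,
    t_max_min: float = 300.0,
    sample_interval_min: float = 30.0,
    noise_sd_log: float = 0.0,
    seed: int = 0,
) -> GrowthCurve:
    """Viable-count curve of a mixture of exponentially growing subpopulations.

    ``subpopulations`` is a list of ``(initial_fraction, doubling_time_min)``;
    ``N(t) = N0 * sum_k f_k 2^(t / tau_k)``, sampled every 30 min by default,
    optionally with multiplicative lognormal counting noise.  A small fast
    subpopulation (an outgrowing suppressor) makes the log-count curve
    convex — the classic biphasic shape.
    """
    if not subpopulations:
        raise ValueError("at least one subpopulation is required")
    fr = np.array([f for f, _ in subpopulations], dtype=float)
    tau = np.array([t for _, t in subpopulations], dtype=float)
    if np.any(fr <= 0) or np.any(tau <= 0):
        raise ValueError("fractions and doubling times must be positive")
    times = np.arange(0.0, t_max_min + 1e-9, sample_interval_min)
    n = n0_cfu_per_ml * (fr[None, :] * np.exp2(times[:, None] / tau[None, :])).sum(axis=1)
    if noise_sd_log > 0:
        rng = np.random.default_rng([int(seed), 99])
        n = n * np.exp(rng.normal(0.0, noise_sd_log, len(n)))
    return GrowthCurve(times, n, list(subpopulations))
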