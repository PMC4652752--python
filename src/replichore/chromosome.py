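"""Circular-genome data model and circular arithmetic.

Everything downstream — binning, LOESS smoothing, terminus analytics, the
fork simulator — works on a single circular chromosome addressed with
0-based base-pair coordinates in ``[0, length_bp)``.  This module holds the
annotation model (origins, polar *ter* sites, highly transcribed slow
zones, replication barriers, *dif*) and the handful of modular-arithmetic
helpers everything else shares.

The bundled default model describes an *E. coli* MG1655-derived chromosome
of 4.64 Mbp carrying both the native origin *oriC* (3.923 Mbp) and the
ectopic origin *oriZ* (0.344 Mbp), the ten polar ter sites terA–terJ, the
seven rRNA operons (rrnA–E, G, H) as replication slow zones, and *dif*.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

DEFAULT_GENOME_LENGTH = 4_640_000
ORIC_BP = 3_923_000
ORIZ_BP = 344_000

CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"
BLOCKS_CLOCKWISE = "blocks_clockwise"
BLOCKS_COUNTERCLOCKWISE = "blocks_counterclockwise"


def _check_position(pos: float, length: float, what: str = "position") -> None:
    if not 0 <= pos < length:
        raise ValueError(f"{what} {pos!r} outside [0, {length})")


def circular_distance(a: float, b: float, length: float) -> float:
    """Shortest arc length between two positions on a circle of size ``length``."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    _check_position(a, length, "a")
    _check_position(b, length, "b")
    d = abs(a - b)
    return min(d, length - d)


def signed_arc_offset(from_pos: float, to_pos: float, length: float) -> float:
    """Signed clockwise offset from ``from_pos`` to ``to_pos`` in ``[-L/2, L/2)``.

    Positive means ``to_pos`` lies clockwise (increasing coordinate) of
    ``from_pos`` along the shorter arc.
    """
    _check_position(from_pos, length, "from_pos")
    _check_position(to_pos, length, "to_pos")
    return (to_pos - from_pos + length / 2) % length - length / 2


def arc_length_cw(start: float, end: float, length: float) -> float:
    """Clockwise arc length from ``start`` to ``end`` (0 when equal)."""
    return (end - start) % length


def in_arc_cw(pos: float, start: float, end: float, length: float) -> bool:
    """True if ``pos`` lies on the clockwise arc from ``start`` to ``end`` (half-open)."""
    return (pos - start) % length < (end - start) % length


def format_mbp(position_bp: float, decimals: int = 3) -> float:
    """Round a bp coordinate to Mbp at ``decimals`` places, half-up.

    Half-up matters for report parity: 3_275_000 bp at one decimal must read
    3.3 Mbp, which binary ``round`` gets wrong.
    """
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(position_bp) / Decimal(1_000_000)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Origin:
    name: str
    position_bp: int


@dataclass(frozen=True)
class TerSite:
    """A polar replication terminator (ter/Tus).

    ``blocking_direction`` names the fork direction that is arrested:
    ``blocks_clockwise`` stops a fork travelling toward increasing
    coordinates.  ``efficiency`` is the per-encounter arrest probability.
    """

    name: str
    position_bp: int
    blocking_direction: str
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.blocking_direction not in (BLOCKS_CLOCKWISE, BLOCKS_COUNTERCLOCKWISE):
            raise ValueError(f"bad blocking_direction {self.blocking_direction!r}")
        if not 0 <= self.efficiency <= 1:
            raise ValueError("ter efficiency must be in [0, 1]")

    def blocks(self, fork_direction: str) -> bool:
        return (self.blocking_direction == BLOCKS_CLOCKWISE) == (fork_direction == CLOCKWISE)


@dataclass(frozen=True)
class SlowZone:
    """A highly transcribed interval where fork speed is locally rescaled.

    A fork moving against ``transcription_direction`` (head-on encounter)
    runs at ``head_on_factor`` times full speed; a co-directional fork at
    ``codirectional_factor``.  The interval is circular and half-open;
    ``start_bp > end_bp`` wraps through zero.
    """

    name: str
    start_bp: int
    end_bp: int
    transcription_direction: str
    head_on_factor: float = 0.25
    codirectional_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.transcription_direction not in (CLOCKWISE, COUNTERCLOCKWISE):
            raise ValueError(f"bad transcription_direction {self.transcription_direction!r}")
        for f in (self.head_on_factor, self.codirectional_factor):
            if not 0 < f <= 1:
                raise ValueError("slow-zone speed factors must be in (0, 1]")

    def length_bp(self, genome_length: int) -> int:
        return (self.end_bp - self.start_bp) % genome_length

    def contains(self, pos: float, genome_length: int) -> bool:
        return in_arc_cw(pos, self.start_bp, self.end_bp, genome_length)

    def speed_factor(self, fork_direction: str) -> float:
        if fork_direction == self.transcription_direction:
            return self.codirectional_factor
        return self.head_on_factor


@dataclass(frozen=True)
class Barrier:
    """A direction-independent pause element (e.g. a tetO/lacO repressor array)."""

    name: str
    position_bp: int
    pause_s: float = 0.0

    def __post_init__(self) -> None:
        if self.pause_s < 0:
            raise ValueError("barrier pause must be nonnegative")


@dataclass(frozen=True)
class Midpoint:
    """An arithmetic midpoint together with the inter-origin arc it bisects."""

    position_bp: float
    arc_from: str
    arc_to: str

    @property
    def position_mbp(self) -> float:
        return format_mbp(self.position_bp, 4)


@dataclass
class ChromosomeConfig:
    """Annotated circular chromosome: the shared input of every stage."""

    length_bp: int = DEFAULT_GENOME_LENGTH
    origins: list[Origin] = field(default_factory=list)
    ter_sites: list[TerSite] = field(default_factory=list)
    slow_zones: list[SlowZone] = field(default_factory=list)
    barriers: list[Barrier] = field(default_factory=list)
    dif_bp: int | None = None
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if not self.origins:
            raise ValueError("at least one origin is required")
        names = [o.name for o in self.origins]
        if len(set(names)) != len(names):
            raise ValueError("origin names must be unique")
        for o in self.origins:
            _check_position(o.position_bp, self.length_bp, f"origin {o.name}")
        for t in self.ter_sites:
            _check_position(t.position_bp, self.length_bp, f"ter {t.name}")
        for z in self.slow_zones:
            _check_position(z.start_bp, self.length_bp, f"zone {z.name} start")
            _check_position(z.end_bp % self.length_bp, self.length_bp, f"zone {z.name} end")
        for b in self.barriers:
            _check_position(b.position_bp, self.length_bp, f"barrier {b.name}")
        if self.dif_bp is not None:
            _check_position(self.dif_bp, self.length_bp, "dif")

    # -- convenience -------------------------------------------------------

    def origin(self, name: str) -> Origin:
        for o in self.origins:
            if o.name == name:
                return o
        raise KeyError(f"no origin named {name!r}")

    def subset_origins(self, names: Sequence[str], label: str | None = None) -> "ChromosomeConfig":
        """A copy of the model keeping only the named origins (strain configuration)."""
        kept = [self.origin(n) for n in names]
        return replace(self, origins=kept, label=label or "+".join(names))

    def midpoints(self) -> list[Midpoint]:
        """Arithmetic midpoints between the configured origin(s)."""
        if len(self.origins) == 1:
            (o,) = self.origins
            pos = (o.position_bp + self.length_bp / 2) % self.length_bp
            return [Midpoint(pos, o.name, o.name)]
        if len(self.origins) == 2:
            a, b = self.origins
            pts = arithmetic_midpoints([a.position_bp, b.position_bp], self.length_bp)
            # first returned point bisects the clockwise arc a -> b
            return [
                Midpoint(pts[0], a.name, b.name),
                Midpoint(pts[1], b.name, a.name),
            ]
        raise ValueError("midpoints are defined for 1 or 2 origins only")

    def to_dict(self) -> dict:
        return {
            "length_bp": self.length_bp,
            "label": self.label,
            "origins": [vars(o) for o in self.origins],
            "ter_sites": [vars(t) for t in self.ter_sites],
            "slow_zones": [vars(z) for z in self.slow_zones],
            "barriers": [vars(b) for b in self.barriers],
            "dif_bp": self.dif_bp,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def arithmetic_midpoints(origins: Sequence[float], length: float) -> list[float]:
    """Midpoint positions implied by one or two origins on a circle.

    One origin: its antipode ``(a + L/2) mod L``.  Two origins: the bisector
    of the clockwise arc from the first to the second origin, then its
    antipode (which bisects the complementary arc).  More than two origins
    are unsupported.
    """
    if not 1 <= len(origins) <= 2:
        raise ValueError("arithmetic midpoints are defined for 1 or 2 origins")
    for p in origins:
        _check_position(p, length)
    if len(origins) == 1:
        return [(origins[0] + length / 2) % length]
    a, b = origins
    m1 = (a + ((b - a) % length) / 2) % length
    m2 = (m1 + length / 2) % length
    # report in the (a->b arc, b->a arc) order
    return [m1, m2]


def default_chromosome() -> ChromosomeConfig:
    """The bundled dual-origin E. coli model (oriC + oriZ, terA–J, rrnA–H, dif)."""
    from . import io

    return io.load_default_annotation()
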