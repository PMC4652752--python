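"""Marker-frequency analysis: per-bin counts to normalized enrichment.

The marker frequency of a locus is its read depth in an exponentially
growing (replicating) sample relative to a non-replicating stationary-phase
control, each scaled by library size.  Origin-proximal loci are
over-represented in the replicating sample, so the enrichment decays from
each active origin toward the terminus.  Multiplicative per-bin biases
(mappability, GC) shared between the two libraries cancel in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DEFAULT_BIN_WIDTH = 1000

MASK_OK = ""
MASK_ZERO_CONTROL = "zero_control"
MASK_USER = "user_exclusion"


@dataclass
class BinnedCoverage:
    """Integer read counts in fixed-width bins on the circular genome."""

    counts: np.ndarray
    bin_width_bp: int = DEFAULT_BIN_WIDTH
    genome_length_bp: int | None = None
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.bin_width_bp <= 0:
            raise ValueError("bin width must be positive")
        if self.genome_length_bp is None:
            self.genome_length_bp = int(self.n_bins * self.bin_width_bp)
        expected = -(-self.genome_length_bp // self.bin_width_bp)  # ceil
        if self.n_bins != expected:
            raise ValueError(
                f"{self.n_bins} bins inconsistent with genome length "
                f"{self.genome_length_bp} at width {self.bin_width_bp}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_bp


@dataclass
class MarkerFrequencyProfile:
    """Per-bin enrichment (replicating / stationary), with masked bins.

    ``mask`` is True where no enrichment is defined (zero control counts or
    a user exclusion); masked bins carry NaN in ``enrichment`` and a reason
    string in ``mask_reason``.  The mask propagates downstream: masked bins
    never contribute to LOESS fits or minima searches.
    """

    enrichment: np.ndarray
    mask: np.ndarray
    bin_width_bp: int = DEFAULT_BIN_WIDTH
    genome_length_bp: int | None = None
    mask_reason: list[str] = field(default_factory=list)
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.enrichment.shape != self.mask.shape:
            raise ValueError("enrichment and mask must have the same shape")
        if self.genome_length_bp is None:
            self.genome_length_bp = int(len(self.enrichment) * self.bin_width_bp)
        if not self.mask_reason:
            self.mask_reason = [MASK_ZERO_CONTROL if m else MASK_OK for m in self.mask]
        ok = self.enrichment[~self.mask]
        if np.any(~np.isfinite(ok)) or np.any(ok < 0):
            raise ValueError("enrichment must be finite and nonnegative on unmasked bins")

    @property
    def n_bins(self) -> int:
        return len(self.enrichment)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_bp


def bin_coverage(
    depth_records: Iterable[tuple[float, float, float]],
    bin_width: int = DEFAULT_BIN_WIDTH,
    genome_length: int | None = None,
    sample_label: str = "",
) -> BinnedCoverage:
    """Apportion per-bp depth records ``(start, end, value)`` into fixed bins.

    ``value`` is a per-bp depth over the half-open interval ``[start, end)``;
    each record contributes ``value * overlap`` to every bin it touches.
    Records crossing the origin of the coordinate system (``end > L``) are
    split.  Records must not overlap one another.  Totals are rounded
    half-up to integers at the end.
    """
    records = list(depth_records)
    if genome_length is None:
        if not records:
            raise ValueError("cannot infer genome length from an empty record list")
        genome_length = int(max(e for _, e, _ in records))
    L = int(genome_length)
    n_bins = -(-L // bin_width)
    acc = np.zeros(n_bins, dtype=float)

    pieces: list[tuple[float, float, float]] = []
    for start, end, value in records:
        if value < 0:
            raise ValueError(f"negative depth value {value} at record ({start}, {end})")
        if end <= start:
            raise ValueError(f"empty or inverted record ({start}, {end})")
        if end - start > L:
            raise ValueError(f"record ({start}, {end}) longer than the genome")
        if not 0 <= start < L:
            raise ValueError(f"record start {start} outside [0, {L})")
        if end > L:  # wraps through the origin of coordinates
            pieces.append((start, L, value))
            pieces.append((0, end - L, value))
        else:
            pieces.append((start, end, value))

    pieces.sort()
    for (s0, e0, _), (s1, e1, _) in zip(pieces, pieces[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping records near position {s1}")

    for s, e, v in pieces:
        i0 = int(s // bin_width)
        i1 = int(np.ceil(e / bin_width))
        idx = np.arange(i0, i1)
        lo = np.maximum(s, idx * bin_width)
        hi = np.minimum(e, (idx + 1) * bin_width)
        acc[idx] += v * (hi - lo)

    counts = np.floor(acc + 0.5).astype(np.int64)
    return BinnedCoverage(counts, bin_width, L, sample_label)


def marker_frequency(
    exp: BinnedCoverage,
    stat: BinnedCoverage,
    exclude: Sequence[int] | np.ndarray | None = None,
) -> MarkerFrequencyProfile:
    """Enrichment ``E_i = (c_i / sum c) / (s_i / sum s)`` over unmasked bins.

    ``exp`` is the replicating (exponential-phase) sample, ``stat`` the
    stationary-phase control.  Bins with zero control counts are masked,
    as are any bin indices in ``exclude``.  Library-size totals are taken
    over the mutually unmasked bins, so the stationary-weighted mean of the
    enrichment is exactly 1 and the result is invariant to rescaling either
    sample by a constant.
    """
    if exp.bin_width_bp != stat.bin_width_bp or exp.n_bins != stat.n_bins:
        raise ValueError("samples must share the same bin structure")
    c = exp.counts.astype(float)
    s = stat.counts.astype(float)
    mask = s == 0
    reasons = [MASK_ZERO_CONTROL if m else MASK_OK for m in mask]
    if exclude is not None:
        for i in np.asarray(exclude, dtype=int):
            mask[i] = True
            reasons[i] = MASK_USER
    if mask.all():
        raise ValueError("all bins are masked")
    C = c[~mask].sum()
    S = s[~mask].sum()
    if C <= 0 or S <= 0:
        raise ValueError("zero total counts in one of the samples")
    enrichment = np.full(exp.n_bins, np.nan)
    enrichment[~mask] = (c[~mask] / C) / (s[~mask] / S)
    return MarkerFrequencyProfile(
        enrichment,
        mask,
        exp.bin_width_bp,
        exp.genome_length_bp,
        reasons,
        sample_label=exp.sample_label,
    )
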