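"""File formats: coverage tables, annotations, profiles and reports.

Coverage comes in as bedGraph (``chrom start end value``, 0-based
half-open, value = per-bp depth) or as a two-column TSV of per-bin counts
(``bin_start<TAB>count``).  Annotations are GFF3 (1-based closed intervals,
converted to the internal 0-based half-open convention) with feature types
``origin``, ``ter``, ``rrn``, ``barrier`` and ``dif``, or a documented
6-column TSV.  Profiles round-trip through TSV at 6 significant digits with
masked bins written as ``NA``.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from . import __version__
from .chromosome import (
    Barrier,
    ChromosomeConfig,
    Origin,
    SlowZone,
    TerSite,
    CLOCKWISE,
    COUNTERCLOCKWISE,
    BLOCKS_CLOCKWISE,
    BLOCKS_COUNTERCLOCKWISE,
)
from .mfa import BinnedCoverage, MarkerFrequencyProfile, bin_coverage, MASK_OK

log = logging.getLogger("replichore")

REPORT_SCHEMA_VERSION = 1

_DIRECTION = {"clockwise": CLOCKWISE, "counterclockwise": COUNTERCLOCKWISE,
              "+": CLOCKWISE, "-": COUNTERCLOCKWISE}
_BLOCK = {"clockwise": BLOCKS_CLOCKWISE, "counterclockwise": BLOCKS_COUNTERCLOCKWISE}


# ---------------------------------------------------------------------------
# coverage

def _sniff_format(path: str | Path, fmt: str | None, kind: str) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower()
    if kind == "coverage":
        return "bedgraph" if suffix in (".bedgraph", ".bg", ".bdg") else "tsv"
    return "gff3" if suffix in (".gff3", ".gff") else "tsv"


def read_coverage(
    path: str | Path,
    fmt: str | None = None,
    bin_width: int = 1000,
    genome_length: int | None = None,
    sample_label: str | None = None,
) -> BinnedCoverage:
    """Read a coverage file into fixed-width bins.

    bedGraph records must be sorted and non-overlapping; a final record
    running past the genome end is treated as wrapping through the origin
    of coordinates and split.  Malformed lines are reported with their line
    number.
    """
    fmt = _sniff_format(path, fmt, "coverage")
    label = sample_label if sample_label is not None else Path(path).stem
    records: list[tuple[float, float, float]] = []
    if fmt == "bedgraph":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
                try:
                    start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: {exc}") from None
                if records and start < records[-1][0]:
                    raise ValueError(f"{path}:{ln}: records are not sorted by start")
                records.append((start, end, value))
        cov = bin_coverage(records, bin_width, genome_length, label)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["bin_start", "count"])
        starts = df["bin_start"].to_numpy()
        expected = np.arange(len(df)) * bin_width
        if not np.array_equal(starts, expected):
            raise ValueError(f"{path}: bin starts must form a complete {bin_width} bp grid")
        counts = df["count"].to_numpy()
        cov = BinnedCoverage(counts, bin_width, genome_length, label)
    else:
        raise ValueError(f"unknown coverage format {fmt!r}")
    log.info("read %d bins from %s (%s)", cov.n_bins, path, fmt)
    return cov


# ---------------------------------------------------------------------------
# annotations

def _gff_attr(feature, key: str, default=None):
    vals = feature.attributes.get(key)
    return vals[0] if vals else default


def read_annotation(path: str | Path, fmt: str | None = None) -> ChromosomeConfig:
    """Read a chromosome model from GFF3 or the 6-column TSV.

    GFF3 feature types used: ``origin``, ``ter`` (attribute ``block`` =
    clockwise|counterclockwise, optional ``efficiency``), ``rrn`` (strand =
    transcription direction, optional ``head_on_factor`` /
    ``codirectional_factor``), ``barrier`` (``pause_s``), ``dif``.  The
    genome length comes from the ``##sequence-region`` pragma.
    """
    fmt = _sniff_format(path, fmt, "annotation")
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "tsv":
        return _read_annotation_tsv(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gff3(path: str | Path) -> ChromosomeConfig:
    length = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                length = int(line.split()[-1])
                break
    if length is None:
        raise ValueError(f"{path}: missing ##sequence-region pragma (genome length)")

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True)
    origins, ters, zones, barriers = [], [], [], []
    dif = None
    for feat in db.all_features():
        name = _gff_attr(feat, "Name", _gff_attr(feat, "ID", feat.featuretype))
        start0 = feat.start - 1  # GFF3 1-based closed -> 0-based half-open
        end0 = feat.end
        if feat.featuretype == "origin":
            origins.append(Origin(name, start0))
        elif feat.featuretype == "ter":
            block = _gff_attr(feat, "block")
            if block not in _BLOCK:
                raise ValueError(f"{path}: ter {name} missing/bad 'block' polarity attribute")
            eff = float(_gff_attr(feat, "efficiency", 1.0))
            ters.append(TerSite(name, start0, _BLOCK[block], eff))
        elif feat.featuretype in ("rrn", "slow_zone"):
            if feat.strand not in ("+", "-"):
                raise ValueError(f"{path}: slow zone {name} needs a strand")
            zones.append(SlowZone(
                name, start0, end0, _DIRECTION[feat.strand],
                head_on_factor=float(_gff_attr(feat, "head_on_factor", 0.25)),
                codirectional_factor=float(_gff_attr(feat, "codirectional_factor", 1.0)),
            ))
        elif feat.featuretype == "barrier":
            barriers.append(Barrier(name, start0, float(_gff_attr(feat, "pause_s", 0.0))))
        elif feat.featuretype == "dif":
            dif = start0
    cfg = ChromosomeConfig(length, origins, ters, zones, barriers, dif,
                           label=Path(path).stem)
    log.info("read annotation %s: %d origins, %d ter, %d slow zones",
             path, len(origins), len(ters), len(zones))
    return cfg


def _read_annotation_tsv(path: str | Path) -> ChromosomeConfig:
    """6-column TSV: type, name, start_bp, end_bp, info1, info2.

    info1/info2 by type — ter: blocking direction, efficiency; rrn:
    transcription direction, head_on_factor[:codirectional_factor];
    barrier: pause_s, unused.  A ``#length=<bp>`` header line is required.
    """
    length = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#length="):
                    length = int(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            rows.append((ln, parts))
    if length is None:
        raise ValueError(f"{path}: missing '#length=<bp>' header")
    origins, ters, zones, barriers = [], [], [], []
    dif = None
    for ln, (ftype, name, start, end, info1, info2) in rows:
        start, end = int(start), int(end)
        if ftype == "origin":
            origins.append(Origin(name, start))
        elif ftype == "ter":
            if info1 not in _BLOCK:
                raise ValueError(f"{path}:{ln}: bad ter polarity {info1!r}")
            ters.append(TerSite(name, start, _BLOCK[info1],
                                float(info2) if info2 != "." else 1.0))
        elif ftype == "rrn":
            factors = info2.split(":")
            zones.append(SlowZone(name, start, end, _DIRECTION[info1],
                                  head_on_factor=float(factors[0]),
                                  codirectional_factor=float(factors[1]) if len(factors) > 1 else 1.0))
        elif ftype == "barrier":
            barriers.append(Barrier(name, start, float(info1)))
        elif ftype == "dif":
            dif = start
        else:
            raise ValueError(f"{path}:{ln}: unknown feature type {ftype!r}")
    return ChromosomeConfig(length, origins, ters, zones, barriers, dif,
                            label=Path(path).stem)


def write_annotation(config: ChromosomeConfig, path: str | Path) -> None:
    """Write a chromosome model as GFF3 (coordinates converted to 1-based closed)."""
    inv_block = {BLOCKS_CLOCKWISE: "clockwise", BLOCKS_COUNTERCLOCKWISE: "counterclockwise"}
    lines = ["##gff-version 3", f"##sequence-region chromosome 1 {config.length_bp}"]

    def row(ftype, start0, end0, strand, attrs):
        return "\t".join(["chromosome", "replichore", ftype, str(start0 + 1),
                          str(end0), ".", strand, ".", attrs])

    for o in config.origins:
        lines.append(row("origin", o.position_bp, o.position_bp + 1, ".",
                         f"ID={o.name};Name={o.name}"))
    for t in config.ter_sites:
        lines.append(row("ter", t.position_bp, t.position_bp + 1, ".",
                         f"ID={t.name};Name={t.name};block={inv_block[t.blocking_direction]};"
                         f"efficiency={t.efficiency:g}"))
    for z in config.slow_zones:
        strand = "+" if z.transcription_direction == CLOCKWISE else "-"
        lines.append(row("rrn", z.start_bp, z.end_bp, strand,
                         f"ID={z.name};Name={z.name};head_on_factor={z.head_on_factor:g};"
                         f"codirectional_factor={z.codirectional_factor:g}"))
    for b in config.barriers:
        lines.append(row("barrier", b.position_bp, b.position_bp + 1, ".",
                         f"ID={b.name};Name={b.name};pause_s={b.pause_s:g}"))
    if config.dif_bp is not None:
        lines.append(row("dif", config.dif_bp, config.dif_bp + 1, ".", "ID=dif;Name=dif"))
    Path(path).write_text("\n".join(lines) + "\n")


def load_default_annotation() -> ChromosomeConfig:
    """The bundled dual-origin E. coli model."""
    ref = resources.files("replichore").joinpath("data/ecoli_dual_origin.gff3")
    with resources.as_file(ref) as p:
        cfg = _read_gff3(p)
    cfg.label = "ecoli_dual_origin"
    return cfg


# ---------------------------------------------------------------------------
# profiles and reports

def write_profile(profile: MarkerFrequencyProfile, path: str | Path) -> None:
    """TSV with bin start, end, enrichment (6 significant digits), mask reason."""
    with open(path, "w") as fh:
        fh.write("# bin_start\tbin_end\tenrichment\tmask\n")
        fh.write(f"# bin_width={profile.bin_width_bp} genome_length={profile.genome_length_bp}\n")
        w = profile.bin_width_bp
        for i in range(profile.n_bins):
            start = i * w
            end = min(start + w, profile.genome_length_bp)
            if profile.mask[i]:
                fh.write(f"{start}\t{end}\tNA\t{profile.mask_reason[i]}\n")
            else:
                fh.write(f"{start}\t{end}\t{profile.enrichment[i]:.6g}\t.\n")


def read_profile(path: str | Path) -> MarkerFrequencyProfile:
    bin_width = genome_length = None
    starts, values, mask, reasons = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#"):
                if "bin_width=" in line:
                    fields = dict(kv.split("=") for kv in line[1:].split() if "=" in kv)
                    bin_width = int(fields["bin_width"])
                    genome_length = int(fields["genome_length"])
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            starts.append(int(parts[0]))
            if parts[2] == "NA":
                values.append(np.nan)
                mask.append(True)
                reasons.append(parts[3])
            else:
                values.append(float(parts[2]))
                mask.append(False)
                reasons.append(MASK_OK)
    if bin_width is None:
        bin_width = starts[1] - starts[0] if len(starts) > 1 else 1000
    return MarkerFrequencyProfile(np.array(values), np.array(mask), bin_width,
                                  genome_length, reasons)


def write_report(report_dict: dict, path: str | Path, *, strain: str = "",
                 config: ChromosomeConfig | None = None,
                 parameters: dict | None = None) -> dict:
    """Wrap an analysis result in the versioned report envelope and write JSON."""
    envelope = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "strain": strain,
        "config_digest": config.digest() if config is not None else None,
        "parameters": parameters or {},
        "result": report_dict,
    }
    Path(path).write_text(json.dumps(envelope, indent=2, sort_keys=True) + "\n")
    return envelope


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
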