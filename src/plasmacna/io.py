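"""Readers and writers for the on-disk formats the pipeline touches.

Dialects:

* bin-count TSV — header ``chrom start end gc mappability repeat_frac count``,
  one file per sample, ``#`` comment lines allowed (``# sample_id=...`` and
  ``# batch_id=...`` carry sample metadata through round trips);
* SEG-like call table — ``sample chrom start end n_bins log2_ratio
  segment_fraction z_cbs lor bcl call size_mb label``;
* UCSC ``cytoBand.txt`` — ``chrom start end name gieStain``;
* cohort TSV — ``sample_id cancer_type figo_stage pfs_months pfs_event
  os_months os_event`` plus optional ``cna_positive`` / ``total_cna_mb``
  columns (filled by the caller when absent).

Malformed rows raise with the 1-based line number of the offending row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import BinGrid, CountProfile, CytobandMap, GenomeBuild

__all__ = [
    "read_bin_counts",
    "write_bin_counts",
    "read_cytobands",
    "write_seg",
    "read_seg",
    "read_cohort",
    "write_cohort",
    "read_positions_bed",
    "read_positions_sam",
]

_BIN_HEADER = ["chrom", "start", "end", "gc", "mappability", "repeat_frac", "count"]
_SEG_HEADER = [
    "sample", "chrom", "start", "end", "n_bins", "log2_ratio",
    "segment_fraction", "z_cbs", "lor", "bcl", "call", "size_mb", "label",
]
_COHORT_HEADER = [
    "sample_id", "cancer_type", "figo_stage",
    "pfs_months", "pfs_event", "os_months", "os_event",
]

VALID_STAGES = ("I", "II", "III", "IV")
VALID_CANCER_TYPES = ("ovarian", "cervical", "endometrial")


def write_bin_counts(path: str | Path, grid: BinGrid, profile: CountProfile) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        if profile.batch_id is not None:
            fh.write(f"# batch_id={profile.batch_id}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_BIN_HEADER)
        for i in range(grid.n_bins):
            w.writerow([
                grid.chrom[i], int(grid.start[i]), int(grid.end[i]),
                f"{grid.gc[i]:.6g}", f"{grid.mappability[i]:.6g}",
                f"{grid.repeat_fraction[i]:.6g}", int(profile.counts[i]),
            ])


def read_bin_counts(
    path: str | Path, genome: GenomeBuild | None = None, bin_size: int | None = None
) -> tuple[BinGrid, CountProfile]:
    """Read one sample's bin-count table; reconstructs grid and profile.

    If ``genome`` is omitted a minimal build is inferred from the bin
    coordinates (each chromosome's length taken as its last bin end, every
    chromosome treated as autosomal unless named chrX/chrY).
    """
    path = Path(path)
    chroms: list[str] = []
    rows: list[tuple[int, int, float, float, float, int]] = []
    sample_id = path.stem
    batch_id: str | None = None
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                meta = line[1:].strip()
                if meta.startswith("sample_id="):
                    sample_id = meta.split("=", 1)[1]
                elif meta.startswith("batch_id="):
                    batch_id = meta.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if header is None:
                if parts != _BIN_HEADER:
                    raise ValueError(f"{path}:{lineno}: expected header {_BIN_HEADER}, got {parts}")
                header = parts
                continue
            if len(parts) != len(_BIN_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_BIN_HEADER)} columns")
            try:
                chroms.append(parts[0])
                rows.append((int(parts[1]), int(parts[2]), float(parts[3]),
                             float(parts[4]), float(parts[5]), int(parts[6])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    start = np.array([r[0] for r in rows], dtype=np.int64)
    end = np.array([r[1] for r in rows], dtype=np.int64)
    if bin_size is None:
        bin_size = int((end - start).max())
    if genome is None:
        lengths: dict[str, int] = {}
        for c, e in zip(chroms, end):
            lengths[c] = max(lengths.get(c, 0), int(e))
        genome = GenomeBuild(
            name="inferred",
            chromosomes=tuple(lengths.items()),
            autosome_names=tuple(c for c in lengths if c not in ("chrX", "chrY")),
        )
    grid = BinGrid(
        genome=genome,
        bin_size=bin_size,
        chrom=np.array(chroms, dtype=object),
        start=start,
        end=end,
        gc=np.array([r[2] for r in rows]),
        mappability=np.array([r[3] for r in rows]),
        repeat_fraction=np.array([r[4] for r in rows]),
        excluded=np.zeros(len(rows), dtype=bool),
    )
    counts = np.array([r[5] for r in rows], dtype=np.int64)
    return grid, CountProfile(sample_id=sample_id, counts=counts, batch_id=batch_id)


def check_same_grid(grids: Sequence[BinGrid]) -> None:
    """Raise naming the first mismatching bin if grids differ."""
    ref = grids[0]
    for g in grids[1:]:
        if g.n_bins != ref.n_bins:
            raise ValueError(f"grid mismatch: {g.n_bins} bins vs {ref.n_bins}")
        same = (g.chrom == ref.chrom) & (g.start == ref.start) & (g.end == ref.end)
        if not same.all():
            i = int(np.nonzero(~same)[0][0])
            raise ValueError(
                f"grid mismatch at bin {i}: {g.chrom[i]}:{g.start[i]}-{g.end[i]} "
                f"vs {ref.chrom[i]}:{ref.start[i]}-{ref.end[i]}"
            )


def read_cytobands(path: str | Path) -> CytobandMap:
    """Read a UCSC cytoBand.txt dialect file (plain tab-separated)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
            try:
                records.append((parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return CytobandMap(records=records)


def write_seg(path: str | Path, calls: Iterable, sample_id: str | None = None) -> None:
    """Write SegmentCall records (see :mod:`plasmacna.cadet`) as a SEG-like TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SEG_HEADER)
        for c in calls:
            seg = c.segment
            w.writerow([
                sample_id if sample_id is not None else getattr(c, "sample_id", "sample"),
                seg.chrom, int(seg.start_bp), int(seg.end_bp), int(seg.n_bins),
                f"{seg.mean_value:.6g}", f"{c.segment_fraction:.8g}",
                f"{c.z_cbs:.6g}", f"{c.lor:.6g}", f"{c.bcl:.6g}",
                c.call, f"{c.size_mb:.6g}", c.label or "",
            ])


def read_seg(path: str | Path):
    """Read a SEG-like call table back as a list of plain dict rows."""
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                if parts != _SEG_HEADER:
                    raise ValueError(f"{path}:{lineno}: bad SEG header")
                header = parts
                continue
            if len(parts) != len(_SEG_HEADER):
                raise ValueError(f"{path}:{lineno}: wrong column count")
            row = dict(zip(header, parts))
            for key in ("start", "end", "n_bins"):
                row[key] = int(row[key])
            for key in ("log2_ratio", "segment_fraction", "z_cbs", "lor", "bcl", "size_mb"):
                row[key] = float(row[key])
            rows.append(row)
    return rows


def read_cohort(path: str | Path) -> list:
    """Read cohort metadata into CohortRecord objects (see cohort module)."""
    from .cohort import CohortRecord

    records = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                if parts[: len(_COHORT_HEADER)] != _COHORT_HEADER:
                    raise ValueError(f"{path}:{lineno}: bad cohort header, expected {_COHORT_HEADER}")
                header = parts
                continue
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: wrong column count")
            row = dict(zip(header, parts))
            if row["cancer_type"] not in VALID_CANCER_TYPES:
                raise ValueError(f"{path}:{lineno}: unknown cancer_type '{row['cancer_type']}'")
            if row["figo_stage"] not in VALID_STAGES:
                raise ValueError(f"{path}:{lineno}: figo_stage '{row['figo_stage']}' not in {VALID_STAGES}")
            try:
                rec = CohortRecord(
                    sample_id=row["sample_id"],
                    cancer_type=row["cancer_type"],
                    figo_stage=row["figo_stage"],
                    pfs_months=float(row["pfs_months"]),
                    pfs_event=int(row["pfs_event"]),
                    os_months=float(row["os_months"]),
                    os_event=int(row["os_event"]),
                    cna_positive=bool(int(row["cna_positive"])) if "cna_positive" in row else False,
                    total_cna_mb=float(row["total_cna_mb"]) if "total_cna_mb" in row else 0.0,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cohort(path: str | Path, records: Iterable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COHORT_HEADER + ["cna_positive", "total_cna_mb"])
        for r in records:
            w.writerow([
                r.sample_id, r.cancer_type, r.figo_stage,
                f"{r.pfs_months:g}", int(r.pfs_event),
                f"{r.os_months:g}", int(r.os_event),
                int(r.cna_positive), f"{r.total_cna_mb:g}",
            ])


def read_positions_bed(path: str | Path) -> list[tuple[str, int]]:
    """Read read-start positions from a BED file (chrom, chromStart used)."""
    positions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            positions.append((parts[0], int(parts[1])))
    return positions


def read_positions_sam(path: str | Path) -> list[tuple[str, int]]:
    """Read mapped-read 5' start positions from a SAM file via pysam."""
    import pysam

    positions = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for read in sam:
            if read.is_unmapped:
                continue
            positions.append((read.reference_name, read.reference_start))
    return positions
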