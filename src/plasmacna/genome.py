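"""Genome model, fixed-width binning and cytoband naming.

The coordinate backbone of the pipeline is a :class:`BinGrid`: an ordered
tiling of each chromosome into non-overlapping fixed-width windows (50 kb by
default) annotated with GC fraction, mappability and repeat content.  All
coordinates are 0-based half-open internally; 1-based forms appear only in
human-readable report text.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .hg19 import HG19_AUTOSOMES, HG19_CHROM_LENGTHS

__all__ = [
    "GenomeBuild",
    "BinGrid",
    "CountProfile",
    "CytobandMap",
    "hg19_build",
    "make_bins",
    "bin_counts_from_positions",
]


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of named chromosomes with lengths.

    ``autosome_names`` identifies the chromosomes that enter autosomal
    denominators (segment fractions, tumour-fraction features); sex
    chromosomes are carried through normalization but never contribute to
    autosomal totals.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    autosome_names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        unknown = set(self.autosome_names) - set(names)
        if unknown:
            raise ValueError(f"autosome_names not in genome: {sorted(unknown)}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


def hg19_build(include_sex: bool = True) -> GenomeBuild:
    """The packaged hg19 build (chr1-22, optionally X and Y)."""
    chroms = [(c, HG19_CHROM_LENGTHS[c]) for c in HG19_AUTOSOMES]
    if include_sex:
        chroms += [("chrX", HG19_CHROM_LENGTHS["chrX"]), ("chrY", HG19_CHROM_LENGTHS["chrY"])]
    return GenomeBuild("hg19", tuple(chroms), HG19_AUTOSOMES)


@dataclass
class BinGrid:
    """Ordered fixed-width bins tiling a genome.

    Arrays are aligned: ``chrom[i], start[i], end[i]`` give the i-th bin in
    genome order.  The last bin of each chromosome may be shorter than
    ``bin_size``.  ``excluded`` marks bins removed from all analysis
    (high-variance / low-mappability / repeat-rich regions).
    """

    genome: GenomeBuild
    bin_size: int
    chrom: np.ndarray          # dtype=object (str)
    start: np.ndarray          # int64
    end: np.ndarray            # int64
    gc: np.ndarray             # float64 in [0,1]
    mappability: np.ndarray    # float64 in [0,1]
    repeat_fraction: np.ndarray
    excluded: np.ndarray       # bool

    def __post_init__(self) -> None:
        n = len(self.chrom)
        for name in ("start", "end", "gc", "mappability", "repeat_fraction", "excluded"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"bin annotation '{name}' length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def autosomal(self) -> np.ndarray:
        """Boolean mask of bins on autosomes."""
        auto = set(self.genome.autosome_names)
        return np.fromiter((c in auto for c in self.chrom), dtype=bool, count=self.n_bins)

    @property
    def usable(self) -> np.ndarray:
        return ~self.excluded

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.chrom == chrom)[0]

    def copy(self) -> "BinGrid":
        return dataclasses.replace(
            self,
            gc=self.gc.copy(),
            mappability=self.mappability.copy(),
            repeat_fraction=self.repeat_fraction.copy(),
            excluded=self.excluded.copy(),
        )

    def grid_hash(self) -> str:
        """A stable fingerprint of coordinates, used to refuse mismatched panels."""
        import hashlib

        h = hashlib.sha256()
        h.update(("|".join(self.chrom.tolist()) + f"|{self.bin_size}").encode())
        h.update(self.start.tobytes())
        h.update(self.end.tobytes())
        return h.hexdigest()[:16]


def make_bins(genome: GenomeBuild, bin_size: int = 50_000) -> BinGrid:
    """Tile every chromosome of ``genome`` into non-overlapping bins.

    Annotations default to gc=0.5, mappability=1, repeat_fraction=0,
    excluded=False until set by the caller or by :func:`exclusion_filter`.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not genome.chromosomes:
        raise ValueError("genome has no chromosomes")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, length in genome.chromosomes:
        pos = 0
        while pos < length:
            chroms.append(name)
            starts.append(pos)
            ends.append(min(pos + bin_size, length))
            pos += bin_size
    n = len(chroms)
    return BinGrid(
        genome=genome,
        bin_size=bin_size,
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        gc=np.full(n, 0.5),
        mappability=np.ones(n),
        repeat_fraction=np.zeros(n),
        excluded=np.zeros(n, dtype=bool),
    )


@dataclass
class CountProfile:
    """Per-bin raw read counts of one sample, aligned to a BinGrid."""

    sample_id: str
    counts: np.ndarray           # int64, >= 0
    batch_id: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def bin_counts_from_positions(
    positions: list[tuple[str, int]] | np.ndarray,
    grid: BinGrid,
    sample_id: str = "sample",
    batch_id: str | None = None,
) -> tuple[CountProfile, int]:
    """Aggregate mapped-read start positions into bin counts.

    A read is assigned to the bin whose half-open interval contains its
    5' start position.  Positions on chromosomes absent from the grid are
    dropped; the number dropped is returned so read conservation can be
    checked (sum of counts + dropped == number of positions).
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    dropped = 0
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        if pos < 0:
            raise ValueError(f"negative position {pos} on {chrom}")
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, pos_list in by_chrom.items():
        idx = grid.chrom_indices(chrom)
        if idx.size == 0:
            dropped += len(pos_list)
            continue
        pos_arr = np.asarray(pos_list, dtype=np.int64)
        chrom_len = grid.end[idx[-1]]
        off = pos_arr[pos_arr < chrom_len]
        dropped += int(pos_arr.size - off.size)
        # bins within a chromosome are uniform width except the last
        which = np.minimum(off // grid.bin_size, idx.size - 1)
        np.add.at(counts, idx[0] + which, 1)
    return CountProfile(sample_id=sample_id, counts=counts, batch_id=batch_id), dropped


@dataclass
class CytobandMap:
    """UCSC-style cytogenetic bands, used to name reported segments."""

    records: list[tuple[str, int, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _name, _stain in self.records:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals = sorted(ivals)
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping cytobands on {chrom}")

    def bands_for(self, chrom: str) -> list[tuple[int, int, str]]:
        out = [(s, e, name) for c, s, e, name, _ in self.records if c == chrom]
        return sorted(out)

    def label(self, chrom: str, start: int, end: int, direction: str) -> str:
        """Cytogenetic label such as ``8q11.1-8q24.3 gain`` or ``11p15.4 loss``."""
        return segment_to_cytoband_label(self, chrom, start, end, direction)


def segment_to_cytoband_label(
    cytobands: CytobandMap, chrom: str, start: int, end: int, direction: str
) -> str:
    """Name a genomic interval by its first and last overlapped cytoband.

    A one-band interval gets the single-band form (``11p15.4 loss``);
    otherwise ``<chrom><first band>-<chrom><last band> <direction>``, with the
    ``chr`` prefix stripped as in conventional karyotype-style reports.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    bands = cytobands.bands_for(chrom)
    if not bands:
        raise ValueError(f"no cytobands for chromosome {chrom}")
    if end <= start:
        raise ValueError("empty interval")
    if start >= bands[-1][1] or end <= bands[0][0]:
        raise ValueError(f"interval [{start},{end}) outside {chrom} bands")
    hit = [name for s, e, name in bands if s < end and e > start]
    if not hit:
        raise ValueError(f"interval [{start},{end}) overlaps no band on {chrom}")
    short = chrom[3:] if chrom.startswith("chr") else chrom
    if len(hit) == 1:
        return f"{short}{hit[0]} {direction}"
    return f"{short}{hit[0]}-{short}{hit[-1]} {direction}"
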