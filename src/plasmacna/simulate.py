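"""Synthetic low-coverage plasma cfDNA bin-count generator.

Emulates the statistical structure the downstream analysis assumes it must
remove or detect:

* smooth multiplicative GC bias g(gc) with g(0.4) = 1;
* low-rank "batch" artifacts shared across samples (flow-cell style higher
  order structure removable by population PCA);
* overdispersed (gamma-Poisson, i.e. negative-binomial) count noise;
* tumour-derived copy-state deviations: a bin overlapping a copy-``c`` event
  at tumour fraction ``f`` has its expected count multiplied by
  ``1 + f*(c - 2)/2`` (the two-population diploid-background mixture),
  weighted by the overlapped fraction of the bin for partial overlaps.

All randomness flows from explicit integer seeds via ``numpy.random``
SeedSequence spawning, so panels and samples are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid, CountProfile, GenomeBuild, make_bins

__all__ = [
    "SimulationConfig",
    "CNAProfile",
    "SimulationTruth",
    "toy_grid",
    "simulate_panel",
    "simulate_sample",
    "simulate_tumor_sample",
    "random_cna_profile",
    "copy_number_multiplier",
    "write_truth",
]

_LOADINGS_TAG = 7_001
_PANEL_TAG = 7_002


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    ``mean_depth`` is the expected read count per 50-kb bin (500 matches the
    low-coverage single-end NIPT-style sequencing being emulated).
    ``dispersion`` is the negative-binomial overdispersion ``d`` in
    ``var = m + d*m**2``; 0 recovers Poisson, and the default 0.002 doubles
    the Poisson variance at the default depth (typical of well-behaved
    shallow-WGS libraries).  ``gc_quad``/``gc_lin`` shape
    the quadratic GC-bias curve ``g(gc) = 1 + gc_lin*(gc-0.4) + gc_quad*(gc-0.4)**2``.
    ``artifact_scales`` are the log-scale magnitudes of the shared low-rank
    batch components.
    """

    grid: BinGrid
    mean_depth: float = 500.0
    gc_lin: float = 0.8
    gc_quad: float = -4.0
    artifact_scales: tuple[float, ...] = (0.08, 0.05)
    dispersion: float = 0.002
    depth_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def gc_bias(self, gc: np.ndarray) -> np.ndarray:
        """Smooth unimodal multiplicative bias, normalized to g(0.4) = 1."""
        x = np.asarray(gc) - 0.4
        g = 1.0 + self.gc_lin * x + self.gc_quad * x**2
        return np.clip(g, 0.05, None)

    def artifact_loadings(self) -> np.ndarray:
        """Shared orthonormal per-bin loadings of the batch components.

        Band-limited "wave" patterns (white noise band-passed to periods of
        roughly 30-300 bins, i.e. 1.5-15 Mb at 50 kb), matching the
        megabase-scale coverage waves higher-order sequencing artifacts
        produce; chromosome-scale drift is deliberately absent.  Derived
        from the config seed only, so panel and case samples live in the
        same artifact subspace (as flow-cell mates would).
        """
        k = len(self.artifact_scales)
        n = self.grid.n_bins
        if k == 0:
            return np.zeros((0, n))
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(np.random.SeedSequence([self.seed, _LOADINGS_TAG]))
        raw = rng.standard_normal((k, n))
        waves = (
            gaussian_filter1d(raw, 30, axis=1, mode="wrap")
            - gaussian_filter1d(raw, 300, axis=1, mode="wrap")
        )
        waves -= waves.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(waves.T)
        return q.T[:k]


@dataclass
class CNAProfile:
    """Non-overlapping copy-number events (copy in {0,1,3,4})."""

    events: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, copy in self.events:
            if end <= start:
                raise ValueError("event end must exceed start")
            if copy not in (0, 1, 3, 4):
                raise ValueError(f"unsupported copy number {copy}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals = sorted(ivals)
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping events on {chrom}")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated case sample."""

    sample_id: str
    tumor_fraction: float
    cna_profile: CNAProfile
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction < 1.0:
            raise ValueError("tumor fraction must be in [0, 1)")


def toy_grid(
    chrom_lengths_mb: tuple[float, ...] = (120.0, 30.0),
    bin_size: int = 50_000,
    gc_range: tuple[float, float] = (0.35, 0.55),
    seed: int = 0,
) -> BinGrid:
    """A small reduced genome for simulation studies.

    GC varies smoothly at the megabase scale (two short-period sine
    harmonics plus mild jitter) so that the GC curve is uncorrelated with
    multi-megabase copy-number events; mappability/repeat annotations are
    ideal except for a sparse 1% of bins given mappability 0.5 so masking
    paths stay exercised.
    """
    chroms = tuple(
        (f"chr{i + 1}", int(mb * 1e6)) for i, mb in enumerate(chrom_lengths_mb)
    )
    genome = GenomeBuild("toy", chroms, tuple(c for c, _ in chroms))
    grid = make_bins(genome, bin_size)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_777]))
    lo, hi = gc_range
    mid, amp = (lo + hi) / 2, (hi - lo) / 2
    x = np.arange(grid.n_bins)
    gc = mid + amp * (0.7 * np.sin(x / 37.0) + 0.3 * np.sin(x / 11.0))
    gc += rng.normal(0, 0.005, grid.n_bins)
    grid.gc[:] = np.clip(gc, 0.2, 0.8)
    bad = rng.random(grid.n_bins) < 0.01
    grid.mappability[bad] = 0.5
    return grid


def copy_number_multiplier(grid: BinGrid, cna: CNAProfile, tumor_fraction: float) -> np.ndarray:
    """Per-bin expected-count multiplier ``1 + f*w_b*(c_b - 2)/2``.

    ``w_b`` is the fraction of bin ``b`` overlapped by the event (partial
    overlaps scale proportionally); bins outside events keep copy 2.
    """
    mult = np.ones(grid.n_bins)
    for chrom, start, end, copy in cna.events:
        if chrom not in grid.genome.chrom_names:
            raise ValueError(f"event chromosome {chrom} not in genome")
        if end > grid.genome.length_of(chrom) or start < 0:
            raise ValueError(f"event [{start},{end}) outside {chrom}")
        idx = grid.chrom_indices(chrom)
        ov = np.minimum(grid.end[idx], end) - np.maximum(grid.start[idx], start)
        w = np.clip(ov, 0, None) / (grid.end[idx] - grid.start[idx])
        mult[idx] += tumor_fraction * w * (copy - 2) / 2.0
    return mult


def _draw_counts(config: SimulationConfig, rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    if config.dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / config.dispersion
    lam = mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)
    return rng.poisson(lam)


def simulate_sample(
    config: SimulationConfig,
    seed: int,
    sample_id: str = "sample",
    cna: CNAProfile | None = None,
    tumor_fraction: float = 0.0,
    batch_id: str | None = None,
) -> CountProfile:
    """Draw one sample's bin counts; a null sample when no CNA is given.

    With identical config and seed, a tumour-fraction-0 case sample is
    bit-identical to the corresponding null sample (same RNG stream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    grid = config.grid
    depth = config.mean_depth * float(np.exp(rng.normal(0, config.depth_cv)))
    v = config.artifact_loadings()
    scores = rng.standard_normal(len(config.artifact_scales))
    log_art = np.zeros(grid.n_bins)
    for lam, u_k, v_k in zip(config.artifact_scales, scores, v):
        log_art += lam * u_k * v_k * np.sqrt(grid.n_bins)
    mean = depth * config.gc_bias(grid.gc) * np.exp(log_art)
    if cna is not None and tumor_fraction > 0:
        mean = mean * copy_number_multiplier(grid, cna, tumor_fraction)
    counts = _draw_counts(config, rng, mean)
    return CountProfile(sample_id=sample_id, counts=counts, batch_id=batch_id)


def panel_sample_seed(config: SimulationConfig, i: int) -> int:
    ss = np.random.SeedSequence([config.seed, _PANEL_TAG, i])
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def simulate_panel(config: SimulationConfig, n_samples: int) -> list[CountProfile]:
    """Reference panel of unaffected samples sharing the config's artifact space."""
    if n_samples < 2:
        raise ValueError("panel needs at least 2 samples")
    return [
        simulate_sample(config, panel_sample_seed(config, i), sample_id=f"panel{i:03d}")
        for i in range(n_samples)
    ]


def simulate_tumor_sample(config: SimulationConfig, truth: SimulationTruth) -> CountProfile:
    """Case sample whose bin means carry the truth's copy-state mixture."""
    return simulate_sample(
        config,
        truth.seed,
        sample_id=truth.sample_id,
        cna=truth.cna_profile,
        tumor_fraction=truth.tumor_fraction,
    )


def random_cna_profile(
    genome: GenomeBuild,
    n_events: int,
    size_range_mb: tuple[float, float],
    seed: int,
    copy_numbers: tuple[int, ...] = (1, 3),
    max_tries: int = 200,
) -> CNAProfile:
    """Place non-overlapping events of uniform-random size on random chromosomes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7_003]))
    lo, hi = (int(size_range_mb[0] * 1e6), int(size_range_mb[1] * 1e6))
    placed: list[tuple[str, int, int, int]] = []
    for _ in range(n_events):
        ok = False
        for _try in range(max_tries):
            chrom, length = genome.chromosomes[rng.integers(len(genome.chromosomes))]
            size = int(rng.integers(lo, hi + 1))
            if size > length:
                continue
            start = int(rng.integers(0, length - size + 1))
            end = start + size
            if any(c == chrom and s < end and e > start for c, s, e, _ in placed):
                continue
            placed.append((chrom, start, end, int(copy_numbers[rng.integers(len(copy_numbers))])))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place a {lo / 1e6:g}-{hi / 1e6:g} Mb event without overlap "
                f"after {max_tries} tries"
            )
    return CNAProfile(events=placed)


def write_truth(prefix: str, truths: list[SimulationTruth]) -> None:
    """Write a truth TSV plus a companion BED of events per sample."""
    with open(f"{prefix}.tsv", "w") as fh:
        fh.write("sample_id\ttumor_fraction\tseed\n")
        for t in truths:
            fh.write(f"{t.sample_id}\t{t.tumor_fraction:g}\t{t.seed}\n")
    with open(f"{prefix}.events.bed", "w") as fh:
        for t in truths:
            for chrom, start, end, copy in t.cna_profile.events:
                fh.write(f"{chrom}\t{start}\t{end}\t{copy}\t{t.sample_id}\n")
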