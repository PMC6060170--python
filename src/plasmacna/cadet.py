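"""CADET-style statistical classification of CBS segments.

For each candidate segment the caller computes:

* the segment fraction — adjusted reads in the segment over adjusted reads
  across all (unmasked) autosomal bins;
* Z_CBS — the MAD-scaled deviation of that fraction from its reference-panel
  distribution (the same bin interval evaluated in every panel sample);
* Z_CHR — the identical statistic for the segment's whole host chromosome,
  used to separate whole-chromosome from subchromosomal events via
  |Z_CBS| < alpha_whole * |Z_CHR|;
* LOR — a Gaussian two-hypothesis log-odds that the observed fraction comes
  from a single-copy gain/loss at the estimated tumour fraction rather than
  from the diploid null;
* BCL — the bootstrap confidence level: the proportion of within-sample
  bootstrap resamples of the segment whose fractions stay beyond the
  z-threshold.

A segment is called iff |Z_CBS| >= 3.95, LOR > 0 and BCL >= 0.99; calls
longer than 10 Mb are reported, and whole-chromosome gains on chr13/18/21
raise the corresponding trisomy flag.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import BinGrid, CytobandMap
from .normalize import NormalizedProfile, ReferencePanel
from .segment import Segment

__all__ = [
    "CadetThresholds",
    "SegmentCall",
    "SampleReport",
    "segment_fraction",
    "z_statistic",
    "chromosome_z",
    "log_odds_ratio",
    "bootstrap_bcl",
    "classify_segment",
    "call_sample",
]

TRISOMY_CHROMS = ("chr13", "chr18", "chr21")


@dataclass(frozen=True)
class CadetThresholds:
    """Decision thresholds of the classification rule.

    ``z_cut`` (3.95 MADs), ``bcl_cut`` (0.99), ``alpha_whole`` (0.8) and the
    1000-resample bootstrap are the published operating point; the
    ``mad_consistency`` factor 1.4826 puts "MADs away from the median" on a
    normal-sigma scale so the quantity behaves as a z-statistic.
    """

    z_cut: float = 3.95
    bcl_cut: float = 0.99
    alpha_whole: float = 0.8
    n_bootstrap: int = 1000
    min_cna_mb: float = 10.0
    mad_consistency: float = 1.4826
    min_tumor_fraction: float = 0.01
    stitch_gap_mb: float = 2.5
    seed: int = 0


@dataclass
class SegmentCall:
    segment: Segment
    segment_fraction: float
    z_cbs: float
    z_chr: float
    lor: float
    bcl: float
    call: str                 # gain | loss | none
    scope: str | None         # subchromosomal | whole_chromosome | None
    size_mb: float
    label: str | None = None

    @property
    def significant(self) -> bool:
        return self.call != "none"


@dataclass
class SampleReport:
    sample_id: str
    calls: list[SegmentCall]
    all_segments: list[SegmentCall] = field(default_factory=list, repr=False)
    trisomy_13: bool = False
    trisomy_18: bool = False
    trisomy_21: bool = False
    estimated_tumor_fraction: float = 0.0

    @property
    def total_cna_mb(self) -> float:
        return float(sum(c.size_mb for c in self.calls))

    @property
    def cna_positive(self) -> bool:
        return bool(self.calls) or self.trisomy_13 or self.trisomy_18 or self.trisomy_21

    def to_json(self, thresholds: CadetThresholds | None = None) -> str:
        doc = {
            "sample_id": self.sample_id,
            "cna_positive": self.cna_positive,
            "total_cna_mb": self.total_cna_mb,
            "trisomy_13": self.trisomy_13,
            "trisomy_18": self.trisomy_18,
            "trisomy_21": self.trisomy_21,
            "estimated_tumor_fraction": self.estimated_tumor_fraction,
            "n_reported_calls": len(self.calls),
            "calls": [
                {
                    "chrom": c.segment.chrom,
                    "start": c.segment.start_bp,
                    "end": c.segment.end_bp,
                    "call": c.call,
                    "scope": c.scope,
                    "size_mb": c.size_mb,
                    "z_cbs": c.z_cbs,
                    "z_chr": c.z_chr,
                    "lor": c.lor,
                    "bcl": c.bcl,
                    "label": c.label,
                }
                for c in self.calls
            ],
        }
        if thresholds is not None:
            doc["thresholds"] = {
                "z_cut": thresholds.z_cut, "bcl_cut": thresholds.bcl_cut,
                "alpha_whole": thresholds.alpha_whole,
                "n_bootstrap": thresholds.n_bootstrap,
                "min_cna_mb": thresholds.min_cna_mb, "seed": thresholds.seed,
            }
        return json.dumps(doc, indent=2)


def segment_fraction(
    adjusted_counts: np.ndarray,
    bin_indices: np.ndarray,
    grid: BinGrid,
    mask: np.ndarray,
) -> float:
    """Share of autosomal adjusted reads falling in the given bins."""
    auto = mask & grid.autosomal
    total = adjusted_counts[auto].sum()
    if total <= 0:
        raise ValueError("zero autosomal adjusted total")
    sel = bin_indices[mask[bin_indices]]
    return float(adjusted_counts[sel].sum() / total)


def z_statistic(
    f_obs: float, ref_median: float, ref_mad: float, thresholds: CadetThresholds
) -> float:
    """MAD-scaled deviation of a segment fraction from the panel reference."""
    if ref_mad <= 0:
        raise ValueError("reference MAD is zero; use a pooled-MAD fallback")
    return (f_obs - ref_median) / (thresholds.mad_consistency * ref_mad)


def chromosome_z(
    profile: NormalizedProfile,
    chrom: str,
    grid: BinGrid,
    panel: ReferencePanel,
    thresholds: CadetThresholds,
) -> float:
    """Z of the whole chromosome, computed exactly like a segment z."""
    idx = grid.chrom_indices(chrom)
    idx = idx[profile.mask[idx]]
    if idx.size == 0:
        raise ValueError(f"no unmasked bins on {chrom}")
    f_obs = segment_fraction(profile.adjusted_counts, idx, grid, profile.mask)
    med, mad = panel.segment_reference(idx)
    return z_statistic(f_obs, med, mad, thresholds)


def log_odds_ratio(
    f_obs: float,
    f_null: float,
    tumor_fraction: float,
    sigma: float,
    direction: str,
    genome_scale: float = 1.0,
) -> float:
    """Gaussian log-odds of the CNA hypothesis against the diploid null.

    The alternative centers the fraction at the single-copy mixture value
    f_null*(1 ± tf/2); the null at f_null.  Because every segment fraction
    shares the autosomal denominator, a sample with genome-wide copy
    imbalance observes all fractions divided by ``genome_scale``
    D = 1 + (tf/2)*(gained share - lost share); both hypotheses are divided
    by D so the test measures the segment's own shift, not the denominator's
    (D = 1, the default, recovers the focal-event form).  Positive LOR means
    the observation sits closer to the CNA hypothesis.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= tumor_fraction < 1.0:
        raise ValueError("tumor_fraction must be in [0,1)")
    if tumor_fraction == 0.0:
        warnings.warn("tumor fraction 0: LOR indeterminate (hypotheses coincide)")
        return 0.0
    sign = 1.0 if direction == "gain" else -1.0
    f_alt = f_null * (1.0 + sign * tumor_fraction / 2.0) / genome_scale
    f_base = f_null / genome_scale
    return (-((f_obs - f_alt) ** 2) + (f_obs - f_base) ** 2) / (2.0 * sigma**2)


def bootstrap_bcl(
    adjusted_counts: np.ndarray,
    segment_bins: np.ndarray,
    chrom_bins: np.ndarray,
    ref_median: float,
    ref_mad: float,
    autosomal_total: float,
    thresholds: CadetThresholds,
) -> float:
    """Bootstrap confidence level of a candidate segment.

    Within-sample procedure: (1) the median shift of the segment's bin
    counts from the rest of its chromosome is computed; (2) subtracting the
    shift from the segment bins gives a read-count baseline, pooled with the
    out-of-segment chromosome bins; (3) a pseudo-segment of the same bin
    length is resampled with replacement from the baseline, the shift is
    added back, and its segment fraction computed; (4) after
    ``n_bootstrap`` rounds, BCL is the proportion of bootstrap fractions
    whose |z| against the panel reference reaches the z threshold.

    Seeding is derived from the run seed plus the segment's bin coordinates,
    so per-segment results do not depend on evaluation order.
    """
    seg = adjusted_counts[segment_bins].astype(float)
    out_mask = ~np.isin(chrom_bins, segment_bins)
    out = adjusted_counts[chrom_bins[out_mask]].astype(float)
    if out.size == 0:
        warnings.warn("segment covers the whole chromosome; baseline from segment itself")
        shift = 0.0
        pool = seg.copy()
    else:
        shift = float(np.median(seg) - np.median(out))
        pool = np.concatenate([seg - shift, out])
    n_seg = seg.size
    seg_sum = seg.sum()
    ss = np.random.SeedSequence(
        [thresholds.seed & 0x7FFFFFFF, int(segment_bins[0]), int(segment_bins[-1])]
    )
    rng = np.random.default_rng(ss)
    draws = rng.integers(0, pool.size, size=(thresholds.n_bootstrap, n_seg))
    boot_sums = pool[draws].sum(axis=1) + shift * n_seg
    boot_frac = boot_sums / (autosomal_total - seg_sum + boot_sums)
    z = (boot_frac - ref_median) / (thresholds.mad_consistency * ref_mad)
    return float(np.mean(np.abs(z) >= thresholds.z_cut))


def classify_segment(
    z_cbs: float, z_chr: float, lor: float, bcl: float,
    thresholds: CadetThresholds = CadetThresholds(),
) -> tuple[str, str | None]:
    """Apply the published decision rule.

    Significant iff |Z_CBS| >= z_cut and LOR > 0 and BCL >= bcl_cut; the
    direction follows the sign of Z_CBS and the event is whole-chromosome
    when |Z_CBS| < alpha_whole * |Z_CHR|.
    """
    for v in (z_cbs, z_chr, lor, bcl):
        if not math.isfinite(v):
            raise ValueError("classification inputs must be finite")
    significant = (
        abs(z_cbs) >= thresholds.z_cut and lor > 0 and bcl >= thresholds.bcl_cut
    )
    if not significant:
        return "none", None
    call = "gain" if z_cbs > 0 else "loss"
    scope = (
        "whole_chromosome"
        if abs(z_cbs) < thresholds.alpha_whole * abs(z_chr)
        else "subchromosomal"
    )
    return call, scope


def _score_interval(
    profile: NormalizedProfile,
    grid: BinGrid,
    panel: ReferencePanel,
    thresholds: CadetThresholds,
    seg: Segment,
    z_chr_cache: dict[str, float],
    tumor_fraction: float,
    genome_scale: float = 1.0,
) -> SegmentCall:
    bins_all = np.arange(seg.start_bin, seg.end_bin)
    bins = bins_all[profile.mask[bins_all]]
    chrom_bins = grid.chrom_indices(seg.chrom)
    chrom_bins = chrom_bins[profile.mask[chrom_bins]]
    auto = profile.mask & grid.autosomal
    autosomal_total = float(profile.adjusted_counts[auto].sum())
    f_obs = segment_fraction(profile.adjusted_counts, bins, grid, profile.mask)
    med, mad = panel.segment_reference(bins)
    z_cbs = z_statistic(f_obs, med, mad, thresholds)
    if seg.chrom not in z_chr_cache:
        z_chr_cache[seg.chrom] = chromosome_z(profile, seg.chrom, grid, panel, thresholds)
    z_chr = z_chr_cache[seg.chrom]
    tf = max(tumor_fraction, thresholds.min_tumor_fraction)
    sigma = thresholds.mad_consistency * mad
    direction = "gain" if z_cbs > 0 else "loss"
    lor = log_odds_ratio(f_obs, med, tf, sigma, direction, genome_scale=genome_scale)
    bcl = bootstrap_bcl(
        profile.adjusted_counts, bins, chrom_bins, med, mad, autosomal_total, thresholds
    )
    call, scope = classify_segment(z_cbs, z_chr, lor, bcl, thresholds)
    return SegmentCall(
        segment=seg,
        segment_fraction=f_obs,
        z_cbs=z_cbs,
        z_chr=z_chr,
        lor=lor,
        bcl=bcl,
        call=call,
        scope=scope,
        size_mb=seg.size_mb,
    )


def _merge_across_gaps(
    calls: list[SegmentCall], profile: NormalizedProfile, stitch_gap_mb: float = 2.5,
    thresholds: "CadetThresholds | None" = None,
) -> list:
    """Group adjacent same-direction significant calls split by small gaps.

    A gap qualifies when it contains no unmasked bins (an exclusion gap) or
    spans less than ``stitch_gap_mb`` — wave artifacts and noise can carve
    short non-significant dips out of one contiguous event, and reporting
    should not split the event on them.  Returns a list mixing untouched
    SegmentCall items with (merged Segment, direction) pairs to rescore.
    """

    z_cut = thresholds.z_cut if thresholds is not None else 3.95

    def gap_ok(a: SegmentCall, b: SegmentCall, between: list[SegmentCall]) -> bool:
        if b.segment.chrom != a.segment.chrom or b.call != a.call:
            return False
        gap_bins = profile.mask[a.segment.end_bin: b.segment.start_bin]
        if not gap_bins.any():
            return True
        gap_mb = (b.segment.start_bp - a.segment.end_bp) / 1e6
        combined_mb = a.size_mb + b.size_mb
        if gap_mb < max(stitch_gap_mb, 0.1 * combined_mb):
            return True
        # intermediate segments that independently show the same aberration
        # by z (same sign, above the cut) but missed another criterion do
        # not break the event: the merged interval is rescored in full
        sign = 1.0 if a.call == "gain" else -1.0
        return bool(between) and all(sign * m.z_cbs >= z_cut for m in between)

    groups: list[list[SegmentCall]] = []
    last_sig_idx: int | None = None
    sig_indices = [i for i, c in enumerate(calls) if c.significant]
    for i in sig_indices:
        c = calls[i]
        if groups and last_sig_idx is not None and gap_ok(
            groups[-1][-1], c, calls[last_sig_idx + 1: i]
        ):
            groups[-1].append(c)
        else:
            groups.append([c])
        last_sig_idx = i
    merged_spans: list[tuple[str, int, int, str]] = []
    for g in groups:
        if len(g) > 1:
            merged_spans.append(
                (g[0].segment.chrom, g[0].segment.start_bin, g[-1].segment.end_bin, g[0].call)
            )
    out: list = []
    emitted: set[int] = set()
    for c in calls:
        span = next(
            (s for s in merged_spans
             if s[0] == c.segment.chrom and s[1] <= c.segment.start_bin and c.segment.end_bin <= s[2]),
            None,
        )
        if span is None:
            out.append(c)
            continue
        if id(span) in emitted:
            continue
        emitted.add(id(span))
        chrom, start_bin, end_bin, direction = span
        bins = np.arange(start_bin, end_bin)
        bins = bins[profile.mask[bins]]
        seg = Segment(
            chrom=chrom,
            start_bin=start_bin,
            end_bin=end_bin,
            n_bins=int(bins.size),
            mean_value=float(np.nanmean(profile.values[start_bin:end_bin])),
        )
        out.append((seg, direction))
    return out


def call_sample(
    profile: NormalizedProfile,
    segments: list[Segment],
    grid: BinGrid,
    panel: ReferencePanel,
    thresholds: CadetThresholds = CadetThresholds(),
    cytobands: CytobandMap | None = None,
    tumor_fraction: float = 0.0,
) -> SampleReport:
    """Score, classify and report every CBS segment of one sample.

    Reported calls are significant segments larger than ``min_cna_mb``
    (strictly, per the "exceeded 10 Mb" reporting rule); whole-chromosome
    gains on chr13/18/21 set trisomy flags regardless of segment size.
    """
    if panel.grid_hash != grid.grid_hash():
        raise ValueError("panel grid hash does not match sample grid")
    from .segment import segments_to_bp

    z_chr_cache: dict[str, float] = {}
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start_bin))
    # First pass: per-segment fractions and z against the panel, used to
    # place the LOR hypotheses on the sample's own renormalized fraction
    # scale (genome-wide copy imbalance shifts every fraction's denominator).
    first: list[tuple[Segment, float, float, float]] = []   # seg, f_obs, med, z
    for seg in ordered:
        bins_all = np.arange(seg.start_bin, seg.end_bin)
        bins = bins_all[profile.mask[bins_all]]
        if bins.size == 0 or not grid.autosomal[bins[0]]:
            continue
        f_obs = segment_fraction(profile.adjusted_counts, bins, grid, profile.mask)
        med, mad = panel.segment_reference(bins)
        if mad <= 0:
            continue
        first.append((seg, f_obs, med, z_statistic(f_obs, med, mad, thresholds)))
    if tumor_fraction > 0:
        # External estimate (e.g. the regression model).  Because fractions
        # sum to one, "a share S gained" and "the complement lost" produce
        # nearly identical profiles; the configurations differ only at
        # second order through the single-copy shift prior.  Each candidate
        # assignment of the z-flagged segments (gains altered, losses
        # altered, both, none — unflagged segments are renormalization
        # shadows) is scored by how well its predicted fraction ratios
        # (1 + d*tf/2)/D fit every segment, and the best D is adopted.
        tf = max(tumor_fraction, thresholds.min_tumor_fraction)
        sse: dict[str, float] = {}
        d_scale: dict[str, float] = {}
        for mode in ("none", "pos", "neg", "both"):
            share = 0.0
            assign: list[int | None] = []
            for _s, f_obs, med, z in first:
                if abs(z) >= thresholds.z_cut:
                    d: int | None = 0
                    if z > 0 and mode in ("pos", "both"):
                        d = 1
                    elif z < 0 and mode in ("neg", "both"):
                        d = -1
                    share += d * med
                else:
                    d = None  # sub-threshold: free direction in scoring
                assign.append(d)
            d_scale[mode] = 1.0 + tf / 2.0 * share
            total = 0.0
            for (_s, f_obs, med, _z), d in zip(first, assign):
                opts = (d,) if d is not None else (-1, 0, 1)
                total += med * min(
                    (f_obs / med - (1.0 + o * tf / 2.0) / d_scale[mode]) ** 2
                    for o in opts
                )
            sse[mode] = total
        # the configurations differ only at order tf^2, which can drown in
        # panel noise; adopt the winner only when it beats every rival by
        # more than the noise floor, else keep the share-weighted compromise
        noise_floor = 0.0
        for seg, _f, med, _z in first:
            bins_all = np.arange(seg.start_bin, seg.end_bin)
            bins = bins_all[profile.mask[bins_all]]
            _m, mad = panel.segment_reference(bins)
            sigma = thresholds.mad_consistency * mad
            noise_floor += sigma**2 / max(med, 1e-12)
        best = min(sse, key=sse.get)
        decisive = all(
            sse[best] + noise_floor < sse[m] for m in sse if m != best
        )
        genome_scale = d_scale[best] if decisive else d_scale["both"]
    else:
        # No external estimate: anchor the diploid baseline at the segments
        # the median-centered log-ratios call unchanged (valid while the
        # altered share is below half the genome), read the denominator
        # scale D off them, and imply the tumour fraction from the shift of
        # the altered segments — the "amount of CNV" route to tumour burden.
        value_tol = 0.05
        base = [(f, med) for s, f, med, _z in first if abs(s.mean_value) < value_tol]
        genome_scale = 1.0
        if base:
            f_sum = sum(f for f, _ in base)
            med_sum = sum(m for _, m in base)
            if f_sum > 0 and med_sum > 0:
                genome_scale = med_sum / f_sum
        shifts = [
            (abs(f * genome_scale / med - 1.0), med)
            for s, f, med, z in first
            if abs(s.mean_value) >= value_tol and abs(z) >= thresholds.z_cut
        ]
        if shifts:
            tf_implied = 2.0 * sum(s * w for s, w in shifts) / sum(w for _, w in shifts)
            tf = float(np.clip(tf_implied, thresholds.min_tumor_fraction, 0.95))
        else:
            tf = thresholds.min_tumor_fraction
    scored = [
        _score_interval(profile, grid, panel, thresholds, seg, z_chr_cache,
                        tf, genome_scale)
        for seg in ordered
    ]
    # merge same-direction significant neighbours separated only by masked bins,
    # then rescore the merged interval so its statistics describe the whole event
    final: list[SegmentCall] = []
    for item in _merge_across_gaps(scored, profile, thresholds.stitch_gap_mb, thresholds):
        if isinstance(item, SegmentCall):
            final.append(item)
        else:
            seg, _direction = item
            segments_to_bp([seg], grid)
            final.append(
                _score_interval(profile, grid, panel, thresholds, seg, z_chr_cache,
                                tf, genome_scale)
            )
    report = SampleReport(sample_id=profile.sample_id, calls=[], all_segments=final)
    for c in final:
        if not c.significant:
            continue
        # A CBS segment that IS the whole chromosome has z_cbs == z_chr, so the
        # scope comparison cannot fire; near-complete chromosome coverage is the
        # complementary whole-chromosome signature.
        chrom_unmasked = int((profile.mask & (grid.chrom == c.segment.chrom)).sum())
        covers_chrom = chrom_unmasked > 0 and c.segment.n_bins >= 0.9 * chrom_unmasked
        if (
            c.call == "gain"
            and c.segment.chrom in TRISOMY_CHROMS
            and (c.scope == "whole_chromosome" or covers_chrom)
        ):
            setattr(report, f"trisomy_{c.segment.chrom[3:]}", True)
        if c.size_mb > thresholds.min_cna_mb:
            if cytobands is not None:
                try:
                    c.label = cytobands.label(
                        c.segment.chrom, c.segment.start_bp, c.segment.end_bp, c.call
                    )
                except ValueError:
                    c.label = None
            report.calls.append(c)
    report.estimated_tumor_fraction = tumor_fraction if tumor_fraction > 0 else tf
    return report
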