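"""Seeded end-to-end simulation studies of the detector's operating points.

These routines run the full pipeline (simulate -> normalize -> segment ->
classify) on the reduced two-chromosome study genome (120 + 30 Mb, 3,000
50-kb bins, depth 500, panel of 20) and measure:

* null specificity — fraction of tumour-free samples with zero reported
  calls larger than 10 Mb;
* spike-in sensitivity — fraction of replicates in which a planted 100-Mb
  copy-3 event at tumour fraction 0.10 is reported with at least 80%
  reciprocal overlap, and that a 9-Mb event at fraction 0.3 is never
  reported (the strict >10 Mb reporting rule);
* tumour-fraction recovery — held-out RMSE and monotonicity of the ridge
  estimator on fractions in [0, 0.3].

Both the test suite and the reproduction script call these, so the reported
operating characteristics always come from a fresh computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cadet import CadetThresholds, SampleReport, call_sample
from .normalize import (
    ExclusionThresholds,
    exclusion_filter,
    fit_reference_panel,
    loess_gc_adjust,
    pca_smooth,
)
from .segment import CbsParams, segment_profile
from .simulate import (
    CNAProfile,
    SimulationConfig,
    SimulationTruth,
    simulate_panel,
    simulate_tumor_sample,
    toy_grid,
)

__all__ = [
    "StudySetup",
    "build_study_setup",
    "run_one_sample",
    "null_specificity_study",
    "spike_sensitivity_study",
    "tf_recovery_study",
]


@dataclass
class StudySetup:
    config: SimulationConfig
    grid: object
    panel: object
    cbs_params: CbsParams
    thresholds: CadetThresholds


def build_study_setup(
    seed: int,
    panel_size: int = 20,
    mean_depth: float = 500.0,
    k: int = 10,
) -> StudySetup:
    """Simulate and fit the shared reference panel for one study seed."""
    grid = toy_grid(seed=seed)
    config = SimulationConfig(grid=grid, mean_depth=mean_depth, seed=seed)
    raw_panel = simulate_panel(config, panel_size)
    grid_f, _ = exclusion_filter(raw_panel, grid, ExclusionThresholds())
    adj = [loess_gc_adjust(p, grid_f) for p in raw_panel]
    panel = fit_reference_panel(adj, grid_f, k=k)
    return StudySetup(
        config=config,
        grid=grid_f,
        panel=panel,
        cbs_params=CbsParams(seed=seed),
        thresholds=CadetThresholds(seed=seed),
    )


def run_one_sample(setup: StudySetup, truth: SimulationTruth) -> SampleReport:
    """Full per-sample pipeline: simulate, normalize, segment, classify."""
    raw = simulate_tumor_sample(setup.config, truth)
    adj = loess_gc_adjust(raw, setup.grid)
    norm = pca_smooth(adj, setup.panel)
    segs = segment_profile(norm.values, norm.mask, setup.grid, setup.cbs_params)
    return call_sample(
        norm, segs, setup.grid, setup.panel, setup.thresholds,
        tumor_fraction=truth.tumor_fraction,
    )


def null_specificity_study(seed: int, n_replicates: int = 20) -> dict:
    """Reported-call counts on tumour-free samples."""
    setup = build_study_setup(seed)
    n_clean = 0
    counts = []
    for r in range(n_replicates):
        truth = SimulationTruth(
            sample_id=f"null{r:02d}", tumor_fraction=0.0,
            cna_profile=CNAProfile(events=[]), seed=seed * 1000 + 101 + r,
        )
        report = run_one_sample(setup, truth)
        counts.append(len(report.calls))
        n_clean += int(len(report.calls) == 0)
    return {
        "n_replicates": n_replicates,
        "n_zero_call": n_clean,
        "call_counts": counts,
        "fraction_zero_call": n_clean / n_replicates,
    }


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def spike_sensitivity_study(
    seed: int,
    n_replicates: int = 20,
    event_mb: float = 100.0,
    tumor_fraction: float = 0.10,
    copy_number: int = 3,
    min_overlap: float = 0.8,
) -> dict:
    """Recovery of a planted event by the full pipeline.

    The event is placed on chr1 (120 Mb) with a replicate-dependent start so
    boundaries vary; a detection requires a reported call of the correct
    direction with >= ``min_overlap`` reciprocal overlap with the truth.
    """
    setup = build_study_setup(seed)
    chrom = "chr1"
    chrom_len = setup.grid.genome.length_of(chrom)
    size = int(event_mb * 1e6)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4_242]))
    hits = 0
    details = []
    direction = "gain" if copy_number > 2 else "loss"
    for r in range(n_replicates):
        start = int(rng.integers(0, chrom_len - size + 1))
        start = (start // 50_000) * 50_000
        truth = SimulationTruth(
            sample_id=f"spike{r:02d}",
            tumor_fraction=tumor_fraction,
            cna_profile=CNAProfile(events=[(chrom, start, start + size, copy_number)]),
            seed=seed * 1000 + 501 + r,
        )
        report = run_one_sample(setup, truth)
        best = 0.0
        for c in report.calls:
            if c.segment.chrom == chrom and c.call == direction:
                best = max(best, _reciprocal_overlap(
                    (start, start + size), (c.segment.start_bp, c.segment.end_bp)
                ))
        hits += int(best >= min_overlap)
        details.append({"start": start, "best_overlap": best,
                        "n_calls": len(report.calls)})
    return {
        "n_replicates": n_replicates,
        "n_detected": hits,
        "fraction_detected": hits / n_replicates,
        "details": details,
    }


def small_event_filter_study(
    seed: int, n_replicates: int = 20, event_mb: float = 9.0, tumor_fraction: float = 0.3
) -> dict:
    """A sub-10-Mb event must never be reported, however significant."""
    setup = build_study_setup(seed)
    chrom = "chr1"
    size = int(event_mb * 1e6)
    reported = 0
    positives = 0
    for r in range(n_replicates):
        start = 30_000_000 + r * 1_000_000
        truth = SimulationTruth(
            sample_id=f"small{r:02d}",
            tumor_fraction=tumor_fraction,
            cna_profile=CNAProfile(events=[(chrom, start, start + size, 3)]),
            seed=seed * 1000 + 801 + r,
        )
        report = run_one_sample(setup, truth)
        reported += len(report.calls)
        positives += int(report.cna_positive)
    return {"n_replicates": n_replicates, "n_reported_calls": reported,
            "n_cna_positive": positives}


def tf_recovery_study(
    seed: int,
    n_train: int = 100,
    n_test: int = 30,
    max_fraction: float = 0.3,
) -> dict:
    """Held-out RMSE and monotone mean recovery of the ridge TF estimator.

    Training and test samples share one fixed CNA profile (a 50-Mb copy-3
    event on chr1 and a 20-Mb copy-1 loss on chr2) with fractions uniform
    in [0, max_fraction].
    """
    from .tumor_fraction import estimate_tumor_fraction, train_tf_model

    grid = toy_grid(seed=seed)
    config = SimulationConfig(grid=grid, seed=seed)
    cna = CNAProfile(events=[
        ("chr1", 10_000_000, 60_000_000, 3),
        ("chr2", 5_000_000, 25_000_000, 1),
    ])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9_191]))

    def make(n, tag):
        out = []
        for i in range(n):
            f = float(rng.uniform(0, max_fraction))
            truth = SimulationTruth(
                sample_id=f"{tag}{i:03d}", tumor_fraction=f, cna_profile=cna,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append((simulate_tumor_sample(config, truth), f))
        return out

    train = make(n_train, "tr")
    test = make(n_test, "te")
    model = train_tf_model(train, grid, regularization=1.0, seed=seed)
    errs = []
    for prof, f in test:
        est, _ = estimate_tumor_fraction(model, prof, grid)
        errs.append(est - f)
    rmse = float(np.sqrt(np.mean(np.square(errs))))
    # monotonicity of the mean estimate over a fixed fraction grid
    grid_f = np.arange(0.0, max_fraction + 1e-9, 0.05)
    means = []
    for f in grid_f:
        ests = []
        for i in range(5):
            truth = SimulationTruth(
                sample_id=f"g{f:.2f}_{i}", tumor_fraction=float(f), cna_profile=cna,
                seed=int(1_000_000 + round(f * 1000) * 100 + i + seed),
            )
            est, _ = estimate_tumor_fraction(
                model, simulate_tumor_sample(config, truth), grid
            )
            ests.append(est)
        means.append(float(np.mean(ests)))
    return {
        "holdout_rmse": rmse,
        "training_rmse": model.training_rmse,
        "fraction_grid": grid_f.tolist(),
        "mean_estimates": means,
        "monotone": bool(np.all(np.diff(means) >= -1e-6)),
    }
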