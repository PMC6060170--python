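"""End-to-end orchestration: panel building, per-sample calling, cohort report.

Stages run in the fixed order exclusion -> LOESS -> panel fit -> PCA smooth
-> CBS -> classification -> tumour fraction -> cohort summary.  Every run
writes a manifest (seeds, thresholds, stage outputs) and is bit-reproducible
for a given config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cadet import CadetThresholds, SampleReport, call_sample
from .cohort import detection_table, pooled_stage_rates
from .genome import BinGrid, CountProfile, CytobandMap
from .io import check_same_grid, read_bin_counts, read_cohort, read_cytobands, write_seg
from .normalize import (
    ExclusionThresholds,
    exclusion_filter,
    fit_reference_panel,
    loess_gc_adjust,
    pca_smooth,
)
from .segment import CbsParams, segment_profile
from .tumor_fraction import TumorFractionModel, estimate_tumor_fraction

__all__ = ["RunConfig", "run_pipeline", "call_one_sample"]


@dataclass
class RunConfig:
    """Validated inputs and parameters of one pipeline run."""

    panel_paths: list[str]
    sample_paths: list[str]
    out_dir: str
    cytoband_path: str | None = None
    cohort_path: str | None = None
    k_components: int = 10
    loess_span: float = 0.3
    exclusion: ExclusionThresholds = field(default_factory=ExclusionThresholds)
    cbs: CbsParams = field(default_factory=CbsParams)
    thresholds: CadetThresholds = field(default_factory=CadetThresholds)
    tf_model: TumorFractionModel | None = None
    threads: int = 1
    seed: int = 0

    def validate(self) -> None:
        if len(self.panel_paths) < 3:
            raise ValueError("need at least 3 panel samples")
        if not self.sample_paths:
            raise ValueError("no case samples given")
        for p in [*self.panel_paths, *self.sample_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def call_one_sample(
    profile: CountProfile,
    grid: BinGrid,
    panel,
    config: RunConfig,
    cytobands: CytobandMap | None,
) -> SampleReport:
    adj = loess_gc_adjust(profile, grid, span=config.loess_span)
    norm = pca_smooth(adj, panel)
    segs = segment_profile(norm.values, norm.mask, grid, config.cbs)
    tf = 0.0
    if config.tf_model is not None:
        tf, _ = estimate_tumor_fraction(config.tf_model, profile, grid)
    return call_sample(
        norm, segs, grid, panel, config.thresholds,
        cytobands=cytobands, tumor_fraction=tf,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the populated output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        loaded = [read_bin_counts(p) for p in config.panel_paths]
        grids = [g for g, _ in loaded]
        check_same_grid(grids)
        grid0 = grids[0]
        panel_profiles = [p for _, p in loaded]
        cytobands = read_cytobands(config.cytoband_path) if config.cytoband_path else None

        stage = "exclusion"
        grid, excl_counts = exclusion_filter(panel_profiles, grid0, config.exclusion)

        stage = "panel_fit"
        adj_panel = [loess_gc_adjust(p, grid, span=config.loess_span) for p in panel_profiles]
        k = min(config.k_components, max(len(adj_panel) - 2, 0))
        panel = fit_reference_panel(adj_panel, grid, k=k)

        stage = "samples"
        sample_dir = out / "samples"
        sample_dir.mkdir(exist_ok=True)

        def _one(path: str) -> SampleReport:
            sgrid, profile = read_bin_counts(path)
            check_same_grid([grid0, sgrid])
            return call_one_sample(profile, grid, panel, config, cytobands)

        if config.threads > 1:
            from concurrent.futures import ThreadPoolExecutor

            with ThreadPoolExecutor(max_workers=config.threads) as pool:
                reports = list(pool.map(_one, config.sample_paths))
        else:
            reports = [_one(p) for p in config.sample_paths]
        for report in reports:
            (sample_dir / f"{report.sample_id}.json").write_text(
                report.to_json(config.thresholds)
            )
            write_seg(sample_dir / f"{report.sample_id}.seg", report.all_segments,
                      sample_id=report.sample_id)

        stage = "cohort"
        cohort_out = {}
        if config.cohort_path:
            records = read_cohort(config.cohort_path)
            by_id = {r.sample_id: r for r in records}
            for rep in reports:
                if rep.sample_id in by_id:
                    by_id[rep.sample_id].cna_positive = rep.cna_positive
                    by_id[rep.sample_id].total_cna_mb = rep.total_cna_mb
            table = detection_table(records)
            pooled = pooled_stage_rates(records)
            table.to_csv(out / "detection_table.tsv", sep="\t")
            pooled.to_csv(out / "pooled_rates.tsv", sep="\t")
            cohort_out = {"n_records": len(records)}

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_panel": len(panel_profiles),
            "n_samples": len(reports),
            "n_bins": int(grid.n_bins),
            "n_excluded_bins": int(grid.excluded.sum()),
            "exclusion_counts": excl_counts,
            "k_components": int(panel.k),
            "thresholds": {
                "z_cut": config.thresholds.z_cut,
                "bcl_cut": config.thresholds.bcl_cut,
                "alpha_whole": config.thresholds.alpha_whole,
                "n_bootstrap": config.thresholds.n_bootstrap,
                "min_cna_mb": config.thresholds.min_cna_mb,
            },
            "cbs": {
                "alpha": config.cbs.alpha,
                "n_permutations": config.cbs.n_permutations,
                "min_width": config.cbs.min_width,
                "merge_tol": config.cbs.merge_tol,
            },
            "sample_reports": [
                {
                    "sample_id": r.sample_id,
                    "cna_positive": r.cna_positive,
                    "total_cna_mb": r.total_cna_mb,
                    "n_calls": len(r.calls),
                }
                for r in reports
            ],
            **cohort_out,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
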