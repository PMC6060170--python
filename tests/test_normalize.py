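"""Exclusion filtering, LOESS GC adjustment and PCA smoothing."""

import numpy as np
import pytest

from plasmacna.genome import CountProfile
from plasmacna.normalize import (
    ExclusionThresholds,
    exclusion_filter,
    fit_reference_panel,
    loess_gc_adjust,
    pca_smooth,
)
from plasmacna.simulate import SimulationConfig, simulate_panel


@pytest.fixture
def clean_panel(small_grid):
    cfg = SimulationConfig(grid=small_grid, mean_depth=800.0, seed=17)
    return simulate_panel(cfg, 12)


class TestExclusionFilter:
    def test_identical_ideal_panel_no_exclusions(self, small_grid):
        prof = CountProfile("a", np.full(small_grid.n_bins, 500))
        grid, counts = exclusion_filter([prof, prof, prof], small_grid)
        assert grid.excluded.sum() == 0
        assert counts == {"high_variance": 0, "low_mappability": 0, "high_repeat": 0}

    def test_zero_mappability_bin_excluded(self, small_grid):
        g = small_grid.copy()
        g.mappability[17] = 0.0
        prof = CountProfile("a", np.full(g.n_bins, 500))
        grid, counts = exclusion_filter([prof, prof], g)
        assert grid.excluded[17]
        assert counts["low_mappability"] == 1

    def test_injected_variance_excluded_at_quantile(self, small_grid, clean_panel):
        j = 123
        noisy = []
        rng = np.random.default_rng(3)
        for p in clean_panel:
            c = p.counts.copy()
            c[j] = max(0, int(c[j] + rng.normal(0, 10 * np.sqrt(c[j]))))
            noisy.append(CountProfile(p.sample_id, c))
        grid, _ = exclusion_filter(noisy, small_grid)
        assert grid.excluded[j]

    def test_all_excluded_errors(self, small_grid):
        g = small_grid.copy()
        g.mappability[:] = 0.0
        prof = CountProfile("a", np.full(g.n_bins, 500))
        with pytest.raises(ValueError):
            exclusion_filter([prof, prof], g)


class TestLoessGcAdjust:
    def test_no_bias_near_identity(self, small_grid):
        rng = np.random.default_rng(5)
        counts = rng.poisson(1000, small_grid.n_bins)
        prof = CountProfile("a", counts)
        adj = loess_gc_adjust(prof, small_grid)
        rel = np.abs(adj.adjusted_counts - counts) / counts
        assert rel.max() < 0.02

    def test_quadratic_bias_inverted(self, small_grid):
        # zero-noise counts = 1000 * g(gc) with the generator's quadratic bias
        cfg = SimulationConfig(grid=small_grid, seed=0)
        counts = np.round(1000 * cfg.gc_bias(small_grid.gc)).astype(int)
        adj = loess_gc_adjust(CountProfile("a", counts), small_grid)
        level = np.median(adj.adjusted_counts)
        assert np.abs(adj.adjusted_counts / level - 1).max() < 0.01

    def test_median_preserved(self, small_grid):
        cfg = SimulationConfig(grid=small_grid, mean_depth=900.0, seed=2)
        prof = simulate_panel(cfg, 2)[0]
        adj = loess_gc_adjust(prof, small_grid)
        assert np.median(adj.adjusted_counts) == pytest.approx(
            np.median(prof.counts), rel=0.05
        )

    def test_deterministic(self, small_grid, clean_panel):
        a = loess_gc_adjust(clean_panel[0], small_grid)
        b = loess_gc_adjust(clean_panel[0], small_grid)
        assert (a.adjusted_counts == b.adjusted_counts).all()

    def test_degenerate_gc_identity_with_warning(self, small_grid):
        g = small_grid.copy()
        g.gc[:] = 0.5
        prof = CountProfile("a", np.full(g.n_bins, 300))
        with pytest.warns(UserWarning, match="degenerate GC"):
            adj = loess_gc_adjust(prof, g)
        assert (adj.adjusted_counts == 300).all()

    def test_too_few_bins_rejected(self, three_bin_grid):
        with pytest.raises(ValueError):
            loess_gc_adjust(CountProfile("a", np.array([1, 2, 3])), three_bin_grid)


class TestReferencePanel:
    def test_k_must_be_below_panel_size(self, small_grid, clean_panel):
        adj = [loess_gc_adjust(p, small_grid) for p in clean_panel]
        with pytest.raises(ValueError):
            fit_reference_panel(adj, small_grid, k=len(adj))

    def test_loadings_orthonormal(self, small_grid, clean_panel):
        adj = [loess_gc_adjust(p, small_grid) for p in clean_panel]
        panel = fit_reference_panel(adj, small_grid, k=3)
        gram = panel.components @ panel.components.T
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_identical_panel_degenerates_gracefully(self, small_grid):
        prof = CountProfile("a", np.full(small_grid.n_bins, 500))
        adj = [loess_gc_adjust(prof, small_grid) for _ in range(5)]
        with pytest.warns(UserWarning, match="degenerate panel"):
            panel = fit_reference_panel(adj, small_grid, k=2)
        assert panel.k == 0
        assert np.all(panel.mad[panel.mask] == 0)

    def test_smoothing_reduces_planted_artifact_variance(self, small_grid):
        cfg = SimulationConfig(grid=small_grid, mean_depth=800.0, seed=23)
        raw = simulate_panel(cfg, 20)
        adj = [loess_gc_adjust(p, small_grid) for p in raw]
        panel = fit_reference_panel(adj, small_grid, k=2)
        # pre-smoothing log-ratio variance vs post-smoothing (LOO residuals)
        pre = np.log2(
            np.stack([p.adjusted_counts for p in adj])[:, panel.mask]
            / np.clip(panel.median[panel.mask] * np.stack(
                [p.adjusted_counts[panel.mask & small_grid.autosomal].sum() for p in adj]
            )[:, None], 1e-12, None)
        )
        pre = pre - pre.mean(axis=0)
        post = np.log2(panel.fractions[:, panel.mask]
                       / np.clip(panel.median[panel.mask], 1e-300, None))
        post = post - post.mean(axis=0)
        assert post.var() <= 0.25 * pre.var()


class TestPcaSmooth:
    @pytest.fixture
    def fitted(self, small_grid, clean_panel):
        adj = [loess_gc_adjust(p, small_grid) for p in clean_panel]
        return fit_reference_panel(adj, small_grid, k=3)

    def test_panel_median_profile_maps_to_zero(self, small_grid, fitted):
        from plasmacna.normalize import NormalizedProfile

        counts = fitted.median * 1e6
        prof = NormalizedProfile("m", counts, fitted.mask.copy())
        out = pca_smooth(prof, fitted)
        assert np.nanmax(np.abs(out.values)) < 1e-9

    def test_own_component_removed(self, small_grid, fitted):
        from plasmacna.normalize import NormalizedProfile

        v = np.zeros(small_grid.n_bins)
        v[fitted.mask] = fitted.components[0]
        counts = fitted.median * np.exp2(0.2 * v) * 1e6
        prof = NormalizedProfile("c", np.where(fitted.mask, counts, 1.0), fitted.mask.copy())
        out = pca_smooth(prof, fitted)
        assert np.nanmax(np.abs(out.values)) < 0.02

    def test_orthogonal_signal_untouched(self, small_grid, fitted):
        from plasmacna.normalize import NormalizedProfile

        rng = np.random.default_rng(11)
        sig = rng.normal(0, 0.05, int(fitted.mask.sum()))
        sig -= fitted.components.T @ (fitted.components @ sig)  # orthogonalize
        counts = np.ones(small_grid.n_bins)
        counts[fitted.mask] = fitted.median[fitted.mask] * np.exp2(sig) * 1e6
        prof = NormalizedProfile("o", counts, fitted.mask.copy())
        out = pca_smooth(prof, fitted)
        # renormalization shifts by a constant; the shape must be intact
        got = out.values[fitted.mask]
        assert np.abs((got - got.mean()) - (sig - sig.mean())).max() < 1e-8

    def test_spiked_segment_survives_smoothing(self, small_grid):
        # artifact-free panel: the spike is orthogonal to the panel subspace
        # by construction (on a 400-bin grid the simulator's wave artifacts
        # share the event's scale, which a 12-sample panel cannot separate)
        cfg = SimulationConfig(grid=small_grid, mean_depth=800.0,
                               artifact_scales=(), seed=17)
        adj = [loess_gc_adjust(p, small_grid) for p in simulate_panel(cfg, 12)]
        panel = fit_reference_panel(adj, small_grid, k=3)
        from plasmacna.simulate import CNAProfile, SimulationTruth, simulate_tumor_sample

        cna = CNAProfile([("c1", 2_000_000, 7_000_000, 3)])  # 100 bins, f=0.2 -> x1.10
        truth = SimulationTruth("s", 0.2, cna, seed=99)
        raw = simulate_tumor_sample(cfg, truth)
        out = pca_smooth(loess_gc_adjust(raw, small_grid), panel)
        spiked = out.values[40:140]
        baseline = np.nanmean(np.concatenate([out.values[:40], out.values[140:400]]))
        assert np.nanmean(spiked) - baseline == pytest.approx(np.log2(1.10), rel=0.2)

    def test_grid_mismatch_rejected(self, fitted):
        from plasmacna.normalize import NormalizedProfile

        prof = NormalizedProfile("x", np.ones(10), np.ones(10, dtype=bool))
        with pytest.raises(ValueError):
            pca_smooth(prof, fitted)

    def test_null_residuals_centered_and_uncorrelated(self, small_grid):
        cfg = SimulationConfig(grid=small_grid, mean_depth=800.0, seed=31)
        raw = simulate_panel(cfg, 12)
        adj = [loess_gc_adjust(p, small_grid) for p in raw]
        panel = fit_reference_panel(adj, small_grid, k=3)
        from plasmacna.simulate import simulate_sample

        meds, acs = [], []
        for r in range(5):
            prof = simulate_sample(cfg, 5_000 + r)
            out = pca_smooth(loess_gc_adjust(prof, small_grid), panel)
            v = out.values[out.mask]
            meds.append(np.median(v))
            acs.append(np.corrcoef(v[:-1], v[1:])[0, 1])
        assert max(abs(m) for m in meds) < 0.01
        assert max(acs) < 0.1


class TestPanelSerialization:
    def test_round_trip_and_grid_hash_guard(self, small_grid, clean_panel, tmp_path):
        from plasmacna.normalize import ReferencePanel

        adj = [loess_gc_adjust(p, small_grid) for p in clean_panel]
        panel = fit_reference_panel(adj, small_grid, k=3)
        path = tmp_path / "panel.npz"
        panel.save(str(path))
        back = ReferencePanel.load(str(path), small_grid)
        assert back.k == panel.k and back.panel_size == panel.panel_size
        assert np.allclose(back.median, panel.median, equal_nan=True)
        assert np.allclose(back.fractions, panel.fractions)
        assert np.allclose(back.components, panel.components)
        other = small_grid.copy()
        other.start = other.start.copy()
        other.start[0] = 7
        with pytest.raises(ValueError, match="hash"):
            ReferencePanel.load(str(path), other)
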