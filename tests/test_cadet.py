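"""Segment fractions, z-statistics, LOR, bootstrap confidence, decision rule."""

import itertools

import numpy as np
import pytest

from plasmacna.cadet import (
    CadetThresholds,
    bootstrap_bcl,
    classify_segment,
    log_odds_ratio,
    segment_fraction,
    z_statistic,
)
from plasmacna.genome import GenomeBuild, make_bins

THR = CadetThresholds()


@pytest.fixture
def forty_bin_grid():
    genome = GenomeBuild("t", (("c1", 2_000_000),), ("c1",))
    return make_bins(genome, 50_000)


class TestSegmentFraction:
    def test_printed_formula_arithmetic(self, forty_bin_grid):
        counts = np.full(40, 100.0)  # autosomal total 4000
        mask = np.ones(40, dtype=bool)
        f = segment_fraction(counts, np.array([3, 4]), forty_bin_grid, mask)
        assert f == pytest.approx(0.05)

    def test_all_bins_gives_one(self, forty_bin_grid):
        counts = np.random.default_rng(0).uniform(50, 150, 40)
        mask = np.ones(40, dtype=bool)
        f = segment_fraction(counts, np.arange(40), forty_bin_grid, mask)
        assert f == pytest.approx(1.0)

    def test_partition_additivity(self, forty_bin_grid):
        counts = np.random.default_rng(1).uniform(50, 150, 40)
        mask = np.ones(40, dtype=bool)
        cuts = [0, 7, 19, 25, 40]
        total = sum(
            segment_fraction(counts, np.arange(a, b), forty_bin_grid, mask)
            for a, b in zip(cuts, cuts[1:])
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_rejected(self, forty_bin_grid):
        with pytest.raises(ValueError):
            segment_fraction(np.zeros(40), np.array([0]), forty_bin_grid,
                             np.ones(40, dtype=bool))


class TestZStatistic:
    def test_at_median_is_zero(self):
        assert z_statistic(0.01, 0.01, 0.001, THR) == 0.0

    def test_decision_boundary(self):
        f = 0.01 + 3.95 * 1.4826 * 0.001
        assert z_statistic(f, 0.01, 0.001, THR) == pytest.approx(3.95)

    def test_hand_computed_panel(self):
        # panel fractions {0.010..0.014}: median 0.012, MAD 0.001
        panel = np.array([0.010, 0.011, 0.012, 0.013, 0.014])
        med = float(np.median(panel))
        mad = float(np.median(np.abs(panel - med)))
        z = z_statistic(0.020, med, mad, THR)
        assert z == pytest.approx((0.020 - 0.012) / (1.4826 * 0.001), rel=1e-12)
        assert z == pytest.approx(5.395, abs=0.001)

    def test_zero_mad_directs_to_fallback(self):
        with pytest.raises(ValueError, match="pooled-MAD"):
            z_statistic(0.01, 0.01, 0.0, THR)


class TestLogOddsRatio:
    def test_null_centered_observation_negative(self):
        for tf in (0.05, 0.2, 0.6):
            assert log_odds_ratio(0.01, 0.01, tf, 0.001, "gain") < 0

    def test_alternative_centered_positive(self):
        f_null, tf = 0.01, 0.2
        f_alt = f_null * (1 + tf / 2)
        assert log_odds_ratio(f_alt, f_null, tf, 0.001, "gain") > 0
        f_alt_loss = f_null * (1 - tf / 2)
        assert log_odds_ratio(f_alt_loss, f_null, tf, 0.001, "loss") > 0

    def test_midpoint_is_zero(self):
        f_null, tf = 0.01, 0.2
        mid = (f_null + f_null * (1 + tf / 2)) / 2
        assert log_odds_ratio(mid, f_null, tf, 0.001, "gain") == pytest.approx(0, abs=1e-9)

    def test_zero_tumor_fraction_indeterminate(self):
        with pytest.warns(UserWarning, match="indeterminate"):
            assert log_odds_ratio(0.012, 0.01, 0.0, 0.001, "gain") == 0.0

    def test_genome_scale_recenters_hypotheses(self):
        # in a high-burden sample the same observed fraction flips sign
        f_null, tf, d = 0.2, 0.1, 1.03
        f_obs = f_null * (1 + tf / 2) / d  # a true gain seen through the denominator
        assert log_odds_ratio(f_obs, f_null, tf, 0.002, "gain") < 0
        assert log_odds_ratio(f_obs, f_null, tf, 0.002, "gain", genome_scale=d) > 0

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            log_odds_ratio(0.01, 0.01, 0.1, 0.0, "gain")


class TestBootstrapBcl:
    def _setup(self, n_chrom=400, depth=1000.0, seg=slice(100, 200), shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        counts = np.full(n_chrom, depth) + rng.normal(0, np.sqrt(depth), n_chrom)
        counts[seg] += shift
        chrom_bins = np.arange(n_chrom)
        seg_bins = np.arange(seg.start, seg.stop)
        total = counts.sum()
        return counts, seg_bins, chrom_bins, total

    def test_noiseless_step_bcl_one(self):
        # +50% step at depth 1000, 100-bin segment, zero noise
        counts = np.full(400, 1000.0)
        counts[100:200] = 1500.0
        seg_bins = np.arange(100, 200)
        ref_med, ref_mad = 0.25, 0.001
        bcl = bootstrap_bcl(counts, seg_bins, np.arange(400), ref_med, ref_mad,
                            counts.sum(), THR)
        assert bcl == 1.0

    def test_null_bcl_small_across_replicates(self):
        thr = CadetThresholds(n_bootstrap=500)
        high = 0
        for rep in range(20):
            counts, seg_bins, chrom_bins, total = self._setup(seed=100 + rep)
            # reference matched to the sampling distribution of the fraction
            # (delta method on f = A/(A+B) with Poisson-scale noise)
            ref_med = 100 / 400
            sigma = np.hypot(0.75 * np.sqrt(100 * 1000), 0.25 * np.sqrt(300 * 1000)) / 400_000
            ref_mad = sigma / 1.4826
            bcl = bootstrap_bcl(counts, seg_bins, chrom_bins, ref_med, ref_mad,
                                total, thr)
            high += bcl > 0.05
        assert high <= 2

    def test_bit_reproducible(self):
        counts, seg_bins, chrom_bins, total = self._setup(shift=300.0, seed=5)
        a = bootstrap_bcl(counts, seg_bins, chrom_bins, 0.25, 0.002, total, THR)
        b = bootstrap_bcl(counts, seg_bins, chrom_bins, 0.25, 0.002, total, THR)
        assert a == b

    def test_invariant_to_uniform_count_scaling(self):
        counts, seg_bins, chrom_bins, total = self._setup(shift=300.0, seed=6)
        a = bootstrap_bcl(counts, seg_bins, chrom_bins, 0.25, 0.002, total, THR)
        b = bootstrap_bcl(counts * 3.0, seg_bins, chrom_bins, 0.25, 0.002,
                          total * 3.0, THR)
        assert a == b

    def test_whole_chromosome_segment_warns(self):
        counts = np.full(50, 1000.0)
        with pytest.warns(UserWarning, match="whole chromosome"):
            bootstrap_bcl(counts, np.arange(50), np.arange(50), 0.5, 0.01,
                          counts.sum() * 2, THR)


class TestClassifyRule:
    def test_printed_examples(self):
        assert classify_segment(4.2, 1.0, 0.8, 0.995) == ("gain", "subchromosomal")
        assert classify_segment(4.2, 6.0, 0.8, 0.995) == ("gain", "whole_chromosome")
        assert classify_segment(3.9, 6.0, 0.8, 0.995) == ("none", None)

    def test_loss_direction(self):
        assert classify_segment(-5.0, -1.0, 0.5, 1.0) == ("loss", "subchromosomal")

    def test_truth_table_sixteen_corners(self):
        # two-sided sweep of the four conditions at representative values
        z_vals = {True: 4.5, False: 3.0}
        lor_vals = {True: 0.5, False: -0.5}
        bcl_vals = {True: 0.995, False: 0.9}
        # whole-chromosome condition |z_cbs| < 0.8*|z_chr|
        zchr_vals = {True: 10.0, False: 1.0}
        for sig_z, pos_lor, high_bcl, whole in itertools.product([True, False], repeat=4):
            call, scope = classify_segment(
                z_vals[sig_z], zchr_vals[whole], lor_vals[pos_lor], bcl_vals[high_bcl]
            )
            if sig_z and pos_lor and high_bcl:
                assert call == "gain"
                assert scope == ("whole_chromosome" if whole else "subchromosomal")
            else:
                assert (call, scope) == ("none", None)

    def test_boundary_values_exact(self):
        thr = CadetThresholds()
        # z exactly at 3.95 is significant (>=); bcl exactly 0.99 passes (>=)
        assert classify_segment(3.95, 0.0, 0.1, 0.99, thr)[0] == "gain"
        # lor exactly 0 fails (> 0 strict)
        assert classify_segment(4.5, 0.0, 0.0, 1.0, thr) == ("none", None)
        # alpha-whole branch strict: |z| == 0.8|z_chr| -> subchromosomal
        assert classify_segment(4.0, 5.0, 1.0, 1.0, thr)[1] == "subchromosomal"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_segment(np.nan, 1.0, 1.0, 1.0)
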