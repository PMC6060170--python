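"""Genome model, binning, cytoband naming, and file round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmacna.genome import (
    CytobandMap,
    GenomeBuild,
    bin_counts_from_positions,
    hg19_build,
    make_bins,
    segment_to_cytoband_label,
)
from plasmacna.hg19 import HG19_CHROM_LENGTHS
from plasmacna.io import (
    check_same_grid,
    read_bin_counts,
    read_cohort,
    read_cytobands,
    read_seg,
    write_bin_counts,
    write_cohort,
    write_seg,
)


class TestMakeBins:
    @pytest.mark.parametrize(
        "length,expected_bins,last",
        [
            (150_000, 3, (100_000, 150_000)),   # exact division
            (120_000, 3, (100_000, 120_000)),   # remainder bin shorter
        ],
    )
    def test_tiling(self, length, expected_bins, last):
        genome = GenomeBuild("t", (("c1", length),), ("c1",))
        grid = make_bins(genome, 50_000)
        assert grid.n_bins == expected_bins
        assert (int(grid.start[-1]), int(grid.end[-1])) == last
        # contiguous non-overlapping tiling
        assert grid.start[0] == 0
        assert (grid.start[1:] == grid.end[:-1]).all()

    def test_hg19_chr21_bin_count(self):
        # independently derived: ceil(48,129,895 / 50,000)
        expected = math.ceil(HG19_CHROM_LENGTHS["chr21"] / 50_000)
        assert expected == 963
        grid = make_bins(hg19_build(), 50_000)
        assert grid.chrom_indices("chr21").size == expected

    def test_annotation_defaults(self, three_bin_grid):
        assert (three_bin_grid.gc == 0.5).all()
        assert (three_bin_grid.mappability == 1).all()
        assert not three_bin_grid.excluded.any()

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            make_bins(GenomeBuild("t", (), ()), 50_000)

    def test_bad_bin_size_rejected(self, one_chrom_genome):
        with pytest.raises(ValueError):
            make_bins(one_chrom_genome, 0)


class TestBinCounts:
    def test_boundary_semantics(self, three_bin_grid):
        prof, dropped = bin_counts_from_positions(
            [("c1", 0), ("c1", 49_999), ("c1", 50_000)], three_bin_grid
        )
        assert prof.counts.tolist() == [2, 1, 0]
        assert dropped == 0

    def test_empty_positions(self, three_bin_grid):
        prof, dropped = bin_counts_from_positions([], three_bin_grid)
        assert prof.counts.sum() == 0 and dropped == 0

    def test_unknown_chrom_dropped_and_conserved(self, three_bin_grid):
        pos = [("c1", 10), ("c7", 10), ("c1", 200_000)]
        prof, dropped = bin_counts_from_positions(pos, three_bin_grid)
        assert prof.counts.sum() + dropped == len(pos)
        assert dropped == 2

    def test_negative_position_rejected(self, three_bin_grid):
        with pytest.raises(ValueError):
            bin_counts_from_positions([("c1", -1)], three_bin_grid)

    def test_uniform_positions_within_binomial_bounds(self, three_bin_grid):
        rng = np.random.default_rng(7)
        n = 10_000
        pos = [("c1", int(p)) for p in rng.integers(0, 150_000, n)]
        prof, _ = bin_counts_from_positions(pos, three_bin_grid)
        # Binomial(10000, 1/3) 99.9% interval
        mean, sd = n / 3, math.sqrt(n * (1 / 3) * (2 / 3))
        lo, hi = mean - 3.29 * sd, mean + 3.29 * sd
        assert all(lo < c < hi for c in prof.counts)

    @given(positions=st.lists(st.integers(min_value=0, max_value=200_000), max_size=50))
    @settings(max_examples=25, deadline=None)
    def test_read_conservation_property(self, positions):
        grid = make_bins(GenomeBuild("t", (("c1", 150_000),), ("c1",)), 50_000)
        pos = [("c1", p) for p in positions]
        prof, dropped = bin_counts_from_positions(pos, grid)
        assert prof.counts.sum() + dropped == len(pos)

    def test_order_independence(self, three_bin_grid):
        pos = [("c1", 10), ("c1", 60_000), ("c1", 110_000), ("c1", 20)]
        a, _ = bin_counts_from_positions(pos, three_bin_grid)
        b, _ = bin_counts_from_positions(pos[::-1], three_bin_grid)
        assert (a.counts == b.counts).all()


class TestCytobandLabels:
    def test_single_band_form(self):
        cyto = CytobandMap(records=[("chr11", 0, 1000, "p15.4", "gneg")])
        assert segment_to_cytoband_label(cyto, "chr11", 100, 900, "loss") == "11p15.4 loss"

    def test_two_band_range(self, toy_cytobands):
        label = segment_to_cytoband_label(toy_cytobands, "chr9", 50, 150, "gain")
        assert label == "9p1-9q1 gain"

    def test_full_chromosome_first_to_last(self, toy_cytobands):
        label = segment_to_cytoband_label(toy_cytobands, "chr9", 0, 200, "loss")
        assert label == "9p1-9q1 loss"

    def test_outside_chromosome_rejected(self, toy_cytobands):
        with pytest.raises(ValueError):
            segment_to_cytoband_label(toy_cytobands, "chr9", 300, 400, "gain")

    def test_label_idempotent(self, toy_cytobands):
        # reconstruct the interval from the label's band boundaries and re-label
        label = segment_to_cytoband_label(toy_cytobands, "chr9", 50, 150, "gain")
        bands = {name: (s, e) for s, e, name in toy_cytobands.bands_for("chr9")}
        first, last = "p1", "q1"
        again = segment_to_cytoband_label(
            toy_cytobands, "chr9", bands[first][0], bands[last][1], "gain"
        )
        assert again == label


class TestRoundTrips:
    def test_bin_counts_round_trip(self, three_bin_grid, tmp_path):
        from plasmacna.genome import CountProfile

        prof = CountProfile("s1", np.array([5, 0, 7]), batch_id="fcA")
        path = tmp_path / "s1.tsv"
        write_bin_counts(path, three_bin_grid, prof)
        grid2, prof2 = read_bin_counts(path)
        assert prof2.sample_id == "s1" and prof2.batch_id == "fcA"
        assert (prof2.counts == prof.counts).all()
        assert (grid2.start == three_bin_grid.start).all()
        assert np.allclose(grid2.gc, three_bin_grid.gc)

    def test_ucsc_cytoband_line(self, tmp_path):
        path = tmp_path / "cyto.txt"
        path.write_text("chr1\t0\t2300000\tp36.33\tgneg\n")
        cyto = read_cytobands(path)
        assert cyto.records == [("chr1", 0, 2_300_000, "p36.33", "gneg")]

    def test_cohort_stage_validation_names_row(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        path.write_text(
            "sample_id\tcancer_type\tfigo_stage\tpfs_months\tpfs_event\tos_months\tos_event\n"
            "P1\tovarian\tIIIB\t10\t1\t20\t0\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_cohort(path)

    def test_cohort_round_trip(self, tmp_path):
        from plasmacna.cohort import CohortRecord

        recs = [CohortRecord("P1", "ovarian", "III", 10.0, 1, 20.0, 0,
                             cna_positive=True, total_cna_mb=565.0)]
        path = tmp_path / "cohort.tsv"
        write_cohort(path, recs)
        back = read_cohort(path)
        assert back == recs

    def test_seg_round_trip(self, three_bin_grid, tmp_path):
        from plasmacna.cadet import SegmentCall
        from plasmacna.segment import Segment, segments_to_bp

        seg = segments_to_bp([Segment("c1", 0, 2, 2, 0.12)], three_bin_grid)[0]
        call = SegmentCall(seg, 0.05, 4.2, 1.0, 0.8, 0.995, "gain",
                           "subchromosomal", seg.size_mb, label="1p1 gain")
        path = tmp_path / "calls.seg"
        write_seg(path, [call], sample_id="s1")
        rows = read_seg(path)
        assert rows[0]["call"] == "gain"
        assert rows[0]["start"] == 0 and rows[0]["end"] == 100_000
        assert rows[0]["bcl"] == pytest.approx(0.995)

    def test_grid_mismatch_names_first_bin(self, three_bin_grid):
        other = three_bin_grid.copy()
        other.start = other.start.copy()
        other.start[1] = 55_000
        with pytest.raises(ValueError, match="bin 1"):
            check_same_grid([three_bin_grid, other])
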