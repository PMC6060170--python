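import numpy as np
import pytest

from plasmacna.genome import BinGrid, GenomeBuild, make_bins


@pytest.fixture
def one_chrom_genome():
    return GenomeBuild("t", (("c1", 150_000),), ("c1",))


@pytest.fixture
def three_bin_grid(one_chrom_genome):
    return make_bins(one_chrom_genome, 50_000)


@pytest.fixture
def small_grid():
    """400-bin two-chromosome grid with a smooth GC track, all bins usable."""
    genome = GenomeBuild("t", (("c1", 15_000_000), ("c2", 5_000_000)), ("c1", "c2"))
    grid = make_bins(genome, 50_000)
    x = np.arange(grid.n_bins)
    grid.gc[:] = 0.45 + 0.1 * np.sin(x / 7.0)
    return grid


@pytest.fixture
def toy_cytobands():
    from plasmacna.genome import CytobandMap

    return CytobandMap(records=[
        ("chr9", 0, 100, "p1", "gneg"),
        ("chr9", 100, 200, "q1", "gpos50"),
    ])
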