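import numpy as np
import pytest

from cnaevo.grid import BinGrid, CopyNumberProfile


@pytest.fixture
def small_grid() -> BinGrid:
    """Two chromosomes, 10 + 6 bins of 10 units."""
    sizes = {"chr1": 100, "chr2": 60}
    return BinGrid.uniform(sizes, 10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def random_profile(grid, rng, low=0, high=6, sample_id="s"):
    return CopyNumberProfile(
        grid, rng.integers(low, high, size=grid.n_bins), sample_id
    )
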