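import numpy as np
import pytest
import scipy.sparse as sp

from chromarch.model import BinGrid, ContactMap, GenomeAssembly


@pytest.fixture
def small_grid() -> BinGrid:
    """One 10-bin chromosome at 100 kb."""
    return BinGrid(GenomeAssembly(("chr1",), (1_000_000,)), 100_000)


@pytest.fixture
def toy_grid6() -> BinGrid:
    """One 6-bin chromosome at 40 kb."""
    return BinGrid(GenomeAssembly(("chr1",), (240_000,)), 40_000)


def dense_to_map(grid: BinGrid, chrom: str, dense: np.ndarray,
                 weights=None) -> ContactMap:
    """Wrap a symmetric dense matrix as a ContactMap (upper triangle kept)."""
    upper = sp.csr_matrix(np.triu(dense))
    w = {chrom: np.asarray(weights, dtype=float)} if weights is not None else None
    return ContactMap(grid, {chrom: upper}, w)


@pytest.fixture
def unit_weights():
    def make(grid: BinGrid, chrom: str):
        return np.ones(grid.n_bins(chrom))
    return make
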