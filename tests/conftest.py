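import numpy as np
import pytest
from scipy import sparse

from perimark.io import CountMatrix
from perimark.simdata import SimConfig, simulate_tissue_counts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Down-scaled study conditions shared by fast tests."""
    return SimConfig(n_tissues=2, n_cells=300, n_genes=400, seed=0)


@pytest.fixture(scope="session")
def lung_sim(small_config):
    """One simulated tissue with ground truth (300 cells, 400 genes)."""
    return simulate_tissue_counts(small_config, "lung", seed=7)


@pytest.fixture()
def random_counts():
    """Factory for small random count matrices."""

    def make(n_genes=20, n_cells=30, seed=0, density=0.3, tissue="test"):
        rng = np.random.default_rng(seed)
        dense = rng.poisson(1.0, size=(n_genes, n_cells))
        dense[rng.random((n_genes, n_cells)) > density] = 0
        dense[0, :] += 1  # ensure no zero-library cell
        genes = [f"g{i:03d}" for i in range(n_genes)]
        cells = [f"c{j:03d}" for j in range(n_cells)]
        return CountMatrix(sparse.csr_matrix(dense), genes, cells, tissue=tissue)

    return make
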