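import numpy as np
import pytest
import scipy.sparse as sp

import zonalspace as zsp


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across read-only tests."""
    params = zsp.SimulationParams(n_cells=80, n_genes=30)
    matrix, truth = zsp.simulate_zonal_counts(params, seed=11)
    return matrix, truth


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """(counts, truth, norm, z, zones) for the small dataset."""
    matrix, truth = small_sim
    norm = zsp.trimmed_quantile_normalize(matrix)
    z = zsp.zscore(norm)
    zc = zsp.zonal_score(z, zsp.default_zmg())
    zones = zsp.assign_zones(zc, barcodes=z.barcodes)
    return matrix, truth, norm, z, zones


def random_count_matrix(rng, n_genes, n_cells, zero_frac=0.3, max_count=40):
    """Dense random count matrix with a controlled zero fraction."""
    counts = rng.integers(1, max_count, size=(n_genes, n_cells))
    counts[rng.random((n_genes, n_cells)) < zero_frac] = 0
    # every cell keeps at least one nonzero count
    for c in range(n_cells):
        if counts[:, c].sum() == 0:
            counts[rng.integers(n_genes), c] = 1
    return zsp.CountMatrix(
        genes=[f"G{i}" for i in range(n_genes)],
        barcodes=[f"B{j}" for j in range(n_cells)],
        counts=sp.csr_matrix(counts),
    )


def zscore_matrix_from_z(z_values, genes=None, barcodes=None, dropout=None):
    """Build a ZScoreMatrix directly from a z matrix, for unit tests of
    consumers that only read z / dropout."""
    z_values = np.asarray(z_values, dtype=float)
    n_genes, n_cells = z_values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"B{j}" for j in range(n_cells)]
    dropout = (
        np.zeros_like(z_values, dtype=bool) if dropout is None else np.asarray(dropout, dtype=bool)
    )
    sd = z_values.std(axis=1, ddof=0)
    return zsp.ZScoreMatrix(
        genes=genes,
        barcodes=barcodes,
        z=z_values,
        dropout=dropout,
        mean_with_dropouts=np.zeros(n_genes),
        sd=np.where(sd == 0, 1.0, sd),
        mean_without_dropouts=np.zeros(n_genes),
        noninformative=sd == 0,
    )
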