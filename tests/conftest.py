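import numpy as np
import pytest

from batchmix.data import CellDataset, MetricParams, knn_search
from batchmix.synth import gaussian_clusters, make_sim_params, nb_reference


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_counts_dataset():
    """3 genes x 4 cells, 2 batches, deterministic."""
    counts = np.array(
        [
            [0, 1, 2, 3],
            [5, 0, 1, 4],
            [2, 2, 2, 2],
        ]
    )
    return CellDataset(
        counts=counts,
        batch=np.array(["a", "a", "b", "b"]),
        celltype=np.array(["t1", "t2", "t1", "t2"]),
        gene_ids=np.array(["g1", "g2", "MT-g3"]),
        cell_ids=np.array(["c1", "c2", "c3", "c4"]),
    )


@pytest.fixture(scope="session")
def mixed_embedding():
    """600-cell, 4-batch single-cluster Gaussian embedding (fully mixed)."""
    return gaussian_clusters(600, n_batches=4, batch_shift=0.0, dim=10, seed=11)


@pytest.fixture(scope="session")
def batched_embedding():
    """500-cell, 2-batch embedding with a strong batch shift."""
    return gaussian_clusters(500, n_batches=2, batch_shift=8.0, dim=10, seed=12)


@pytest.fixture(scope="session")
def small_graph(mixed_embedding):
    return knn_search(mixed_embedding.embedding, 90)


@pytest.fixture(scope="session")
def small_params():
    return MetricParams(k=90, k_min=30, b_min=30, k_mm=120, n_pcs=10)


@pytest.fixture(scope="session")
def sim_reference():
    """Simulated NB reference with known ground truth (moderate size)."""
    return nb_reference(n_genes=200, n_cells=800, n_celltypes=2, n_batches=2,
                        de_fraction=0.3, lfc_scale=1.5, phi=0.5, seed=3)
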