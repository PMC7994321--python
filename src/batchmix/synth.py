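"""Synthetic fixture generators for metric testing and benchmarking.

Two families of fixtures:

* :func:`gaussian_clusters` -- low-dimensional Gaussian-cluster embeddings
  with batch and cell-type labels and a tunable batch mean shift; these test
  the embedding-based metrics directly, without any count data.
* :func:`make_sim_params` / :func:`nb_reference` -- constructed NB
  simulation parameters with gene- and cell-type-specific batch log2 fold
  changes, and a simulated reference count dataset drawn from them.
"""

from __future__ import annotations

import numpy as np

from .data import CellDataset
from .simulate import SimulationParameters, simulate_counts

__all__ = ["gaussian_clusters", "make_sim_params", "nb_reference"]


def gaussian_clusters(
    n_cells: int,
    n_batches: int = 2,
    n_celltypes: int = 1,
    batch_shift: float = 0.0,
    celltype_sep: float = 10.0,
    dim: int = 10,
    sigma: float = 1.0,
    seed: int = 0,
) -> CellDataset:
    """Embedding-only dataset of isotropic Gaussian cell-type clusters.

    Cell types sit at mutually distant centres (pairwise separation
    ``celltype_sep``); batches within each cell type are shifted by
    ``batch_shift`` along a common direction.  ``batch_shift = 0`` gives
    perfectly mixed batches; large shifts give separated batches.  Labels
    are assigned uniformly at random (seeded).
    """
    rng = np.random.default_rng(seed)
    batch = rng.integers(0, n_batches, size=n_cells)
    celltype = rng.integers(0, n_celltypes, size=n_cells)
    centers = np.zeros((n_celltypes, dim))
    for t in range(n_celltypes):
        # orthogonal-ish center placement
        centers[t, t % dim] = celltype_sep * (1 + t // dim)
    shift_dir = np.zeros(dim)
    shift_dir[-1] = 1.0
    X = (
        centers[celltype]
        + batch[:, None] * batch_shift * shift_dir[None, :]
        + rng.normal(scale=sigma, size=(n_cells, dim))
    )
    return CellDataset(
        embedding=X,
        batch=np.array([f"batch{b}" for b in batch]),
        celltype=np.array([f"ct{t}" for t in celltype]),
    )


def make_sim_params(
    n_genes: int = 400,
    n_celltypes: int = 3,
    n_batches: int = 2,
    de_fraction: float = 0.25,
    lfc_scale: float = 1.0,
    mean_range: tuple[float, float] = (2.0, 50.0),
    celltype_lfc_scale: float = 1.0,
    phi: float | np.ndarray = 0.5,
    seed: int = 0,
) -> SimulationParameters:
    """Construct ground-truth NB simulation parameters.

    Per-gene baselines are log-uniform over ``mean_range``; a fraction of
    genes gets cell-type-specific baseline shifts (scale
    ``celltype_lfc_scale``) so cell types are separable; ``de_fraction`` of
    genes per cell type carry batch log2 fold changes drawn from
    ``Normal(0, lfc_scale)`` for each non-reference batch.  Size factors are
    log-normal with mean 1.
    """
    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes))
    beta0 = np.tile(np.log(base)[:, None], (1, n_celltypes))
    # half the genes vary across cell types
    ct_genes = rng.random(n_genes) < 0.5
    beta0[ct_genes] += rng.normal(
        scale=celltype_lfc_scale, size=(int(ct_genes.sum()), n_celltypes)
    ) * np.log(2.0)
    lfc = np.zeros((n_genes, n_celltypes, n_batches))
    for b in range(1, n_batches):
        affected = rng.random((n_genes, n_celltypes)) < de_fraction
        lfc[:, :, b] = np.where(
            affected, rng.normal(scale=lfc_scale, size=(n_genes, n_celltypes)), 0.0
        )
    sf = np.exp(rng.normal(scale=0.25, size=512))
    sf /= sf.mean()
    phi_arr = np.full(n_genes, float(phi)) if np.isscalar(phi) else np.asarray(phi, float)
    return SimulationParameters(
        phi=phi_arr,
        beta0=beta0,
        lfc=lfc,
        size_factors=sf,
        celltype_props=np.full(n_celltypes, 1.0 / n_celltypes),
        batch_props=np.full(n_batches, 1.0 / n_batches),
    )


def nb_reference(
    n_genes: int = 400,
    n_cells: int = 1500,
    n_celltypes: int = 3,
    n_batches: int = 2,
    de_fraction: float = 0.25,
    lfc_scale: float = 1.0,
    phi: float = 0.5,
    mean_range: tuple[float, float] = (2.0, 50.0),
    seed: int = 0,
) -> tuple[CellDataset, SimulationParameters]:
    """Simulated NB reference dataset plus the ground truth it was drawn from
    (batch strength theta = 1)."""
    params = make_sim_params(
        n_genes=n_genes,
        n_celltypes=n_celltypes,
        n_batches=n_batches,
        de_fraction=de_fraction,
        lfc_scale=lfc_scale,
        phi=phi,
        mean_range=mean_range,
        seed=seed,
    )
    ref = simulate_counts(params, theta=1.0, n_cells=n_cells, seed=seed + 1)
    return ref, params
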