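"""Cell-type-level and global batch-effect metrics.

* ``kbet`` -- per-cell-type chi-squared rejection rate comparing local
  neighbourhood batch composition with the cell type's global composition.
* ``graph_connectivity`` -- mean fraction of each cell type covered by the
  largest connected component of its induced kNN subgraph.
* ``asw_batch`` -- 1 - |average silhouette width| with batch as the cluster
  label, per cell type.
* ``pcr`` -- variance-weighted batch R^2 over the top principal components
  of HVG log-expression (global fraction of variance attributable to batch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2

from .data import CellDataset, MetricParams, compute_pca, knn_search, select_hvg
from .results import MetricResult, make_group_result

__all__ = [
    "kbet",
    "graph_connectivity",
    "asw_batch",
    "pcr",
    "CellTypeGraph",
    "SilhouetteResult",
    "PcrComponents",
]


@dataclass
class CellTypeGraph:
    celltype: object
    n_cells: int
    components: list[int]
    lcc_size: int


@dataclass
class SilhouetteResult:
    per_cell_s: np.ndarray
    per_celltype_asw: dict
    score: float


@dataclass
class PcrComponents:
    pc_variances: np.ndarray
    r2_per_pc: np.ndarray
    score: float


# ---------------------------------------------------------------------------
# kBET
# ---------------------------------------------------------------------------


def kbet(
    embedding: np.ndarray,
    batch: np.ndarray,
    celltype: np.ndarray,
    params: MetricParams | None = None,
    test_size: float = 0.1,
    seed: int = 0,
    k0: int | None = None,
    as_mixing: bool = False,
) -> MetricResult:
    """Per-cell-type chi-squared rejection rate of local batch composition.

    For each cell type, neighbourhoods of size
    ``k0 = ceil(0.25 * mean per-batch size within the cell type)`` are drawn
    among the cell type's own cells around a seeded random subset of them
    (``test_size`` of them, at least 25 where possible) and their batch
    counts tested against the dataset-global batch proportions (Pearson
    chi-squared, df = B - 1; zero-expectation batches are pooled).  The
    per-cell-type score is the fraction of tests with p < ``alpha_kbet``;
    high rejection indicates a batch effect (direction -1).  With
    ``as_mixing=True``, 1 - rejection rate is reported instead.
    """
    params = params or MetricParams()
    batch = np.asarray(batch)
    celltype = np.asarray(celltype)
    levels, global_counts = np.unique(batch, return_counts=True)
    if len(levels) < 2:
        raise ValueError("kbet requires at least 2 batches")
    props = global_counts / global_counts.sum()  # dataset-global composition
    codes_all = np.searchsorted(levels, batch)
    rng = np.random.default_rng(seed)
    per_group: dict = {}
    sizes: dict = {}
    for ct in np.unique(celltype):
        idx = np.flatnonzero(celltype == ct)
        sizes[ct] = len(idx)
        n_present = len(np.unique(batch[idx]))
        k_eff = k0 if k0 is not None else int(np.ceil(0.25 * len(idx) / n_present))
        k_eff = max(2, min(k_eff, len(idx) - 1))
        sub_graph = knn_search(np.asarray(embedding)[idx], k_eff)
        exp = props * k_eff
        if np.any(exp == 0):  # defensive: pool empty-expectation batches
            pool_into = np.argmin(np.where(exp > 0, exp, np.inf))
            exp[pool_into] += exp[exp == 0].sum()
        keep = exp > 0
        n_tests = min(len(idx), max(int(np.ceil(test_size * len(idx))), 25))
        tested = rng.choice(len(idx), size=n_tests, replace=False)
        codes = codes_all[idx]
        rejected = 0
        for c in tested:
            obs = np.bincount(codes[sub_graph.indices[c]], minlength=len(levels))
            stat = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
            p = chi2.sf(stat, df=keep.sum() - 1)
            rejected += p < params.alpha_kbet
        rate = rejected / n_tests
        per_group[ct] = 1.0 - rate if as_mixing else rate
    res = make_group_result("kbet", per_group, sizes, {"test_size": test_size, "k0": k0})
    if as_mixing:
        res.direction = +1
    return res


# ---------------------------------------------------------------------------
# graph connectivity
# ---------------------------------------------------------------------------


def _knn_adjacency(embedding: np.ndarray, k: int):
    graph = knn_search(np.asarray(embedding), k)
    n = graph.n_cells
    rows = np.repeat(np.arange(n), k)
    cols = graph.indices.ravel()
    adj = coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    return ((adj + adj.T) > 0).tocsr()  # undirected union of directed kNN edges


def graph_connectivity(
    embedding: np.ndarray,
    celltype: np.ndarray,
    params: MetricParams | None = None,
    return_components: bool = False,
):
    """Mean LCC fraction of per-cell-type induced kNN subgraphs.

    The kNN graph (``k = params.k_graph``) is built on the full dataset and
    made undirected; for each cell type the subgraph induced by its cells is
    scored as largest-connected-component size over cell-type size.  The
    global score is the unweighted mean over cell types (direction +1); 1
    means every cell type is fully connected.
    """
    params = params or MetricParams()
    celltype = np.asarray(celltype)
    adj = _knn_adjacency(embedding, params.k_graph)
    per_group: dict = {}
    sizes: dict = {}
    details: list[CellTypeGraph] = []
    for ct in np.unique(celltype):
        idx = np.flatnonzero(celltype == ct)
        sizes[ct] = len(idx)
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        comp_sizes = np.bincount(labels, minlength=n_comp)
        lcc = int(comp_sizes.max())
        per_group[ct] = lcc / len(idx)
        details.append(
            CellTypeGraph(ct, len(idx), sorted(comp_sizes.tolist(), reverse=True), lcc)
        )
    res = make_group_result("graph", per_group, sizes, {"k_graph": params.k_graph})
    # Eq-style global: unweighted mean over cell types
    res.global_score = float(np.mean(list(per_group.values())))
    if return_components:
        return res, details
    return res


# ---------------------------------------------------------------------------
# batch ASW
# ---------------------------------------------------------------------------


def asw_batch(
    embedding: np.ndarray,
    batch: np.ndarray,
    celltype: np.ndarray,
) -> MetricResult:
    """1 - |mean silhouette width| with batch as cluster label, per cell type.

    Within each cell type: ``a_i`` = mean distance of cell ``i`` to all other
    cells of its batch, ``b_i`` = minimum over other batches of the mean
    distance to that batch, ``s_i = (b_i - a_i) / max(a_i, b_i)``.  A cell
    alone in its batch gets ``s_i = 0``; cell types with a single batch are
    skipped with a warning.  Per-cell-type score is ``1 - |mean s_i|``; the
    global score is the cell-count-weighted mean (direction +1).
    """
    embedding = np.asarray(embedding, dtype=float)
    batch = np.asarray(batch)
    celltype = np.asarray(celltype)
    per_group: dict = {}
    sizes: dict = {}
    all_s = np.full(len(batch), np.nan)
    for ct in np.unique(celltype):
        idx = np.flatnonzero(celltype == ct)
        levels = np.unique(batch[idx])
        if len(levels) < 2:
            warnings.warn(f"cell type {ct!r} has a single batch; skipped in asw")
            continue
        D = squareform(pdist(embedding[idx]))
        codes = np.searchsorted(levels, batch[idx])
        s = np.zeros(len(idx))
        for i in range(len(idx)):
            same = codes == codes[i]
            n_same = same.sum() - 1
            if n_same == 0:
                s[i] = 0.0  # singleton batch within the cell type
                continue
            a = D[i, same].sum() / n_same  # excludes the zero self-distance
            b = min(D[i, codes == lv].mean() for lv in range(len(levels)) if lv != codes[i])
            s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
        all_s[idx] = s
        per_group[ct] = 1.0 - abs(float(s.mean()))
        sizes[ct] = len(idx)
    if not per_group:
        raise ValueError("no cell type has >= 2 batches; asw undefined")
    res = make_group_result("asw", per_group, sizes)
    res.params["silhouette"] = SilhouetteResult(all_s, {k: 1 - v for k, v in per_group.items()}, res.global_score)
    return res


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------


def _r2_vs_batch(scores: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """R^2 of each PC score column against the batch variable.

    Two batches: squared Pearson correlation with a 0/1 indicator.  More
    batches: R^2 from least-squares projection on the one-hot batch design
    (equivalently 1 - SSE/SST after removing batch means).
    """
    levels = np.unique(batch)
    n = len(batch)
    centered = scores - scores.mean(axis=0)
    sst = (centered**2).sum(axis=0)
    sst = np.where(sst > 0, sst, np.inf)
    if len(levels) == 2:
        ind = (batch == levels[1]).astype(float)
        ind_c = ind - ind.mean()
        denom = np.sqrt((ind_c**2).sum() * sst)
        r = (centered * ind_c[:, None]).sum(axis=0) / denom
        return r**2
    resid = centered.copy()
    for lv in levels:
        mask = batch == lv
        resid[mask] -= resid[mask].mean(axis=0)
    return 1.0 - (resid**2).sum(axis=0) / sst


def pcr(
    ds: CellDataset,
    params: MetricParams | None = None,
    return_components: bool = False,
):
    """Principal-component regression batch score.

    PCA of the log-expression of the ``n_hvg`` most variable genes; for each
    of the top ``n_pcs_pcr`` components the batch R^2 is computed and the
    score is ``sum(var_i * R2_i) / sum(var_i)`` over those components
    (direction -1; 0 = no batch-associated variance).  Fewer available
    components than requested are used as-is.
    """
    params = params or MetricParams()
    if ds.logexpr is None:
        raise ValueError("pcr requires logexpr")
    genes = select_hvg(ds, min(params.n_hvg, ds.n_genes))
    n_pcs = min(params.n_pcs_pcr, len(genes), ds.n_cells - 1)
    scores, var_exp = compute_pca(ds, n_pcs, genes=genes)
    r2 = _r2_vs_batch(scores, np.asarray(ds.batch))
    value = float((var_exp * r2).sum() / var_exp.sum())
    res = MetricResult(
        metric="pcr",
        level="global",
        direction=-1,
        global_score=value,
        params={"n_hvg": len(genes), "n_pcs_pcr": n_pcs},
    )
    if return_components:
        return res, PcrComponents(var_exp, r2, value)
    return res
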