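"""Data model, file IO, preprocessing, kNN search and dataset perturbations.

The central container is :class:`CellDataset`, a genes x cells count matrix
with per-cell batch (and optionally cell-type) labels, an optional
log-normalized expression matrix and an optional low-dimensional embedding.
All downstream metrics operate either on the embedding or on ``logexpr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CellDataset:
    """Gene x cell expression data with per-cell annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes x cells.  May be ``None`` for
        embedding-only datasets.
    batch
        Per-cell categorical batch label (length ``n_cells``).
    celltype
        Optional per-cell cell-type label.
    logexpr
        Log-normalized expression, genes x cells (see :func:`normalize_log`).
    embedding
        Optional cells x D real matrix.
    gene_ids, cell_ids
        String identifiers; generated if not given.
    """

    counts: np.ndarray | None = None
    batch: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    celltype: np.ndarray | None = None
    logexpr: np.ndarray | None = None
    embedding: np.ndarray | None = None
    gene_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.batch = np.asarray(self.batch)
        if self.celltype is not None:
            self.celltype = np.asarray(self.celltype)
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
        if self.logexpr is not None:
            self.logexpr = np.asarray(self.logexpr, dtype=float)
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
        if self.gene_ids is None and self.n_genes is not None:
            self.gene_ids = np.array([f"gene{i}" for i in range(self.n_genes)])
        else:
            self.gene_ids = None if self.gene_ids is None else np.asarray(self.gene_ids)
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell{i}" for i in range(self.n_cells)])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
        self.validate()

    # -- shape helpers ------------------------------------------------------

    @property
    def n_cells(self) -> int:
        if self.counts is not None:
            return self.counts.shape[1]
        if self.logexpr is not None:
            return self.logexpr.shape[1]
        if self.embedding is not None:
            return self.embedding.shape[0]
        return len(self.batch)

    @property
    def n_genes(self) -> int | None:
        if self.counts is not None:
            return self.counts.shape[0]
        if self.logexpr is not None:
            return self.logexpr.shape[0]
        return None

    @property
    def batches(self) -> np.ndarray:
        """Distinct batch levels, in sorted order."""
        return np.unique(self.batch)

    @property
    def celltypes(self) -> np.ndarray:
        if self.celltype is None:
            raise ValueError("dataset has no cell-type labels")
        return np.unique(self.celltype)

    def validate(self) -> None:
        n = self.n_cells
        if len(self.batch) != n:
            raise ValueError(
                f"batch labels ({len(self.batch)}) do not match cell count ({n})"
            )
        if self.celltype is not None and len(self.celltype) != n:
            raise ValueError("celltype labels do not match cell count")
        if self.counts is not None and self.logexpr is not None:
            if self.counts.shape != self.logexpr.shape:
                raise ValueError("counts and logexpr shapes disagree")
        if self.embedding is not None and self.embedding.shape[0] != n:
            raise ValueError("embedding rows do not match cell count")
        if self.counts is not None and self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    def copy(self) -> "CellDataset":
        def _c(x):
            return None if x is None else np.array(x, copy=True)

        return CellDataset(
            counts=_c(self.counts),
            batch=np.array(self.batch, copy=True),
            celltype=_c(self.celltype),
            logexpr=_c(self.logexpr),
            embedding=_c(self.embedding),
            gene_ids=_c(self.gene_ids),
            cell_ids=_c(self.cell_ids),
        )

    def subset_cells(self, idx: np.ndarray) -> "CellDataset":
        idx = np.asarray(idx)
        return CellDataset(
            counts=None if self.counts is None else self.counts[:, idx],
            batch=self.batch[idx],
            celltype=None if self.celltype is None else self.celltype[idx],
            logexpr=None if self.logexpr is None else self.logexpr[:, idx],
            embedding=None if self.embedding is None else self.embedding[idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "CellDataset":
        idx = np.asarray(idx)
        return CellDataset(
            counts=None if self.counts is None else self.counts[idx],
            batch=self.batch,
            celltype=self.celltype,
            logexpr=None if self.logexpr is None else self.logexpr[idx],
            embedding=self.embedding,
            gene_ids=None if self.gene_ids is None else self.gene_ids[idx],
            cell_ids=self.cell_ids,
        )


@dataclass
class NeighborGraph:
    """Per-cell ordered nearest neighbours in an embedding.

    ``indices[c]`` holds the ``k`` nearest neighbours of cell ``c`` (self
    excluded), distance-ascending with ties broken by cell index;
    ``distances[c]`` the matching Euclidean distances.
    """

    indices: np.ndarray
    distances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances shapes disagree")
        if np.any(np.diff(self.distances, axis=1) < 0):
            raise ValueError("distances must be non-decreasing along rows")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class MetricParams:
    """Shared metric parameters with the benchmark's defaults."""

    k: int = 200
    k_min: int = 80
    b_min: int = 80
    k_mm: int = 300
    k_pos: int = 5
    n_pcs: int = 10
    n_pcs_pcr: int = 100
    n_hvg: int = 1000
    k_graph: int = 5
    alpha_kbet: float = 0.05
    perplexity: int = 30

    def __post_init__(self) -> None:
        for name in (
            "k",
            "k_min",
            "b_min",
            "k_mm",
            "k_pos",
            "n_pcs",
            "n_pcs_pcr",
            "n_hvg",
            "k_graph",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_min > self.k:
            raise ValueError("k_min must not exceed k")
        if self.k_pos > self.k_mm:
            raise ValueError("k_pos must not exceed k_mm")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    dense = np.asarray(counts, dtype=float)
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("counts must be integers")
    if dense.min() < 0:
        raise ValueError("counts must be non-negative")
    return np.round(dense).astype(np.int64)


def _labels_from_frame(
    meta: pd.DataFrame, batch_col: str, celltype_col: str | None
) -> tuple[np.ndarray, np.ndarray | None]:
    if batch_col not in meta.columns:
        raise KeyError(f"metadata lacks batch column {batch_col!r}")
    batch = meta[batch_col].to_numpy()
    celltype = None
    if celltype_col is not None:
        if celltype_col not in meta.columns:
            raise KeyError(f"metadata lacks cell-type column {celltype_col!r}")
        celltype = meta[celltype_col].to_numpy()
    return batch, celltype


def load_dataset(
    source: str | Path,
    batch_col: str = "batch",
    celltype_col: str | None = None,
    metadata: str | Path | None = None,
) -> CellDataset:
    """Read a count dataset from H5AD, a dense CSV/TSV or an MTX triplet.

    ``source`` may be a ``.h5ad`` file, a dense genes x cells ``.csv``/``.tsv``
    (header row = cell ids, first column = gene ids; requires ``metadata``),
    or a directory containing ``matrix.mtx``, ``genes.tsv``, ``barcodes.tsv``
    and a cell metadata table (``metadata.tsv`` unless ``metadata`` is given).
    The metadata table must contain ``batch_col`` (and ``celltype_col`` when
    requested), one row per cell.
    """
    source = Path(source)
    if source.suffix == ".h5ad":
        import anndata as ad

        adata = ad.read_h5ad(source)
        counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
        if hasattr(counts, "toarray"):
            counts = counts.toarray()
        counts = _check_counts(np.asarray(counts).T)  # anndata is cells x genes
        batch, celltype = _labels_from_frame(adata.obs, batch_col, celltype_col)
        return CellDataset(
            counts=counts,
            batch=batch,
            celltype=celltype,
            gene_ids=adata.var_names.to_numpy(),
            cell_ids=adata.obs_names.to_numpy(),
        )
    if source.is_dir():
        from scipy.io import mmread

        counts = _check_counts(np.asarray(mmread(source / "matrix.mtx").todense()))
        gene_ids = pd.read_csv(source / "genes.tsv", sep="\t", header=None)[0].to_numpy()
        cell_ids = pd.read_csv(source / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
        meta_path = Path(metadata) if metadata is not None else source / "metadata.tsv"
        meta = pd.read_csv(meta_path, sep="\t")
        batch, celltype = _labels_from_frame(meta, batch_col, celltype_col)
        if counts.shape[0] != len(gene_ids) or counts.shape[1] != len(cell_ids):
            raise ValueError("MTX matrix dimensions do not match gene/cell files")
        if len(meta) != len(cell_ids):
            raise ValueError("metadata rows do not match cell count")
        return CellDataset(
            counts=counts, batch=batch, celltype=celltype,
            gene_ids=gene_ids, cell_ids=cell_ids,
        )
    if source.suffix in (".csv", ".tsv"):
        sep = "," if source.suffix == ".csv" else "\t"
        table = pd.read_csv(source, sep=sep, index_col=0)
        counts = _check_counts(table.to_numpy())
        if metadata is None:
            raise ValueError("dense matrix input requires a metadata table")
        meta = pd.read_csv(metadata, sep="\t")
        batch, celltype = _labels_from_frame(meta, batch_col, celltype_col)
        if len(meta) != counts.shape[1]:
            raise ValueError("metadata rows do not match cell count")
        return CellDataset(
            counts=counts,
            batch=batch,
            celltype=celltype,
            gene_ids=table.index.to_numpy().astype(str),
            cell_ids=table.columns.to_numpy().astype(str),
        )
    raise ValueError(f"unrecognized dataset source: {source}")


def save_h5ad(ds: CellDataset, path: str | Path) -> None:
    """Write a dataset to H5AD (counts in ``layers['counts']``)."""
    import anndata as ad

    obs = pd.DataFrame({"batch": ds.batch}, index=ds.cell_ids.astype(str))
    if ds.celltype is not None:
        obs["celltype"] = ds.celltype
    X = (ds.logexpr if ds.logexpr is not None else ds.counts).T
    adata = ad.AnnData(X=np.asarray(X, dtype=float), obs=obs)
    adata.var_names = [str(g) for g in ds.gene_ids]
    if ds.counts is not None:
        adata.layers["counts"] = ds.counts.T
    if ds.embedding is not None:
        adata.obsm["X_pca"] = ds.embedding
    adata.write_h5ad(Path(path))


def save_mtx(ds: CellDataset, outdir: str | Path) -> None:
    """Write counts as an MTX triplet plus a metadata TSV."""
    from scipy.io import mmwrite
    from scipy.sparse import csc_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ds.counts is None:
        raise ValueError("dataset has no counts")
    mmwrite(outdir / "matrix.mtx", csc_matrix(ds.counts))
    pd.Series(ds.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(ds.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = pd.DataFrame({"batch": ds.batch})
    if ds.celltype is not None:
        meta["celltype"] = ds.celltype
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _mad_outliers(x: np.ndarray, nmads: float) -> np.ndarray:
    """Boolean mask of values beyond nmads MADs from the median (either side).

    The MAD is scaled by 1.4826 for normal consistency; with MAD = 0 any
    deviation from the median is an outlier.
    """
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if not np.isfinite(nmads):
        return np.zeros(len(x), dtype=bool)
    return np.abs(x - med) > nmads * mad


def qc_filter(
    ds: CellDataset,
    nmads: float = 2.5,
    min_cells_per_gene: int = 20,
    mito_prefix: str = "MT-",
) -> CellDataset:
    """Remove outlier cells and rarely detected genes.

    Cells whose total count, detected-gene count or mitochondrial fraction
    lies more than ``nmads`` MADs from the median (either direction) are
    dropped; genes detected in fewer than ``min_cells_per_gene`` of the
    remaining cells are dropped.  Filtering uses raw (not log) totals.
    """
    if ds.counts is None:
        raise ValueError("qc_filter requires counts")
    counts = ds.counts
    totals = counts.sum(axis=0)
    detected = (counts > 0).sum(axis=0)
    is_mito = np.array([str(g).upper().startswith(mito_prefix.upper()) for g in ds.gene_ids])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, counts[is_mito].sum(axis=0) / np.maximum(totals, 1), 0.0)
    bad = (
        _mad_outliers(totals.astype(float), nmads)
        | _mad_outliers(detected.astype(float), nmads)
        | _mad_outliers(mito_frac, nmads)
    )
    keep_cells = np.flatnonzero(~bad)
    if keep_cells.size == 0:
        raise ValueError("qc_filter removed every cell; relax nmads")
    out = ds.subset_cells(keep_cells)
    n_detected = (out.counts > 0).sum(axis=1)
    keep_genes = np.flatnonzero(n_detected >= min_cells_per_gene)
    return out.subset_genes(keep_genes)


def normalize_log(ds: CellDataset, pseudocount: float = 1.0) -> CellDataset:
    """Log2-normalize counts using library-size factors scaled to mean 1.

    ``logexpr[g, c] = log2(counts[g, c] / sf_c + pseudocount)`` where
    ``sf_c = libsize_c / mean(libsize)``.
    """
    if ds.counts is None:
        raise ValueError("normalize_log requires counts")
    libsize = ds.counts.sum(axis=0).astype(float)
    if np.any(libsize == 0):
        raise ValueError("cell with zero total count; run qc_filter first")
    sf = libsize / libsize.mean()
    out = ds.copy()
    out.logexpr = np.log2(ds.counts / sf + pseudocount)
    return out


def size_factors(ds: CellDataset) -> np.ndarray:
    """Library-size factors scaled to mean 1."""
    if ds.counts is None:
        raise ValueError("size_factors requires counts")
    libsize = ds.counts.sum(axis=0).astype(float)
    return libsize / libsize.mean()


def select_hvg(ds: CellDataset, n: int = 1000) -> np.ndarray:
    """Indices of the ``n`` most variable genes of ``logexpr``.

    Ordered variance-descending; ties broken by ascending gene index.
    """
    if ds.logexpr is None:
        raise ValueError("select_hvg requires logexpr")
    if n > ds.n_genes:
        raise ValueError("n exceeds gene count")
    var = ds.logexpr.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")
    return order[:n]


def compute_pca(
    ds: CellDataset, n_pcs: int, genes: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of cell-wise log-expression.

    Returns the cells x ``n_pcs`` score matrix and each component's share of
    total variance.  Components are sign-fixed so the largest-magnitude
    loading entry is positive, making the output deterministic.
    """
    if ds.logexpr is None:
        raise ValueError("compute_pca requires logexpr")
    X = ds.logexpr if genes is None else ds.logexpr[np.asarray(genes)]
    X = X.T.astype(float)  # cells x genes
    n_cells, n_genes = X.shape
    if n_pcs > min(n_cells, n_genes):
        raise ValueError("n_pcs exceeds matrix rank bound")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading entry positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    scores = U[:, :n_pcs] * s[:n_pcs]
    total = (s**2).sum()
    var_explained = (s[:n_pcs] ** 2) / total if total > 0 else np.zeros(n_pcs)
    return scores, var_explained


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------


def knn_search(embedding: np.ndarray, k: int, chunk: int = 2048) -> NeighborGraph:
    """Exact Euclidean k-nearest neighbours, self excluded.

    Rows are distance-ascending; ties are broken by ascending cell index
    (stable sort).  Brute-force all-pairs distances, chunked over query rows.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError("embedding must be cells x D")
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    sq = (X**2).sum(axis=1)
    indices = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k), dtype=float)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * X[start:stop] @ X.T
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[rows - start, rows] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        indices[start:stop] = order
        distances[start:stop] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return NeighborGraph(indices=indices, distances=distances, k=k)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def permute_batch_labels(
    batch: np.ndarray, fraction: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Randomly permute the labels within a random ``fraction`` of positions.

    ``round(fraction * n)`` positions are selected uniformly at random and
    their labels shuffled among themselves; the global label multiset is
    preserved for every fraction.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    batch = np.asarray(batch)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(batch)
    m = int(round(fraction * n))
    out = batch.copy()
    if m == 0:
        return out
    pos = rng.choice(n, size=m, replace=False)
    out[pos] = out[pos][rng.permutation(m)]
    return out


def downsample_batch(
    ds: CellDataset,
    celltype: object,
    batch: object,
    remove_fraction: float,
    seed: int | np.random.Generator,
) -> CellDataset:
    """Remove a random fraction of cells from one (cell type, batch) stratum."""
    if not 0.0 <= remove_fraction <= 1.0:
        raise ValueError("remove_fraction must be in [0, 1]")
    if ds.celltype is None:
        raise ValueError("dataset has no cell-type labels")
    stratum = np.flatnonzero((ds.celltype == celltype) & (ds.batch == batch))
    if stratum.size == 0:
        raise ValueError(f"stratum ({celltype!r}, {batch!r}) is empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_remove = int(round(remove_fraction * stratum.size))
    removed = rng.choice(stratum, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(ds.n_cells), removed)
    return ds.subset_cells(keep)
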