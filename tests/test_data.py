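import numpy as np
import pandas as pd
import pytest

from batchmix.data import (
    CellDataset,
    MetricParams,
    compute_pca,
    downsample_batch,
    knn_search,
    load_dataset,
    normalize_log,
    permute_batch_labels,
    qc_filter,
    save_h5ad,
    save_mtx,
    select_hvg,
)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def test_mtx_roundtrip(tiny_counts_dataset, tmp_path):
    save_mtx(tiny_counts_dataset, tmp_path / "mtx")
    ds = load_dataset(tmp_path / "mtx", batch_col="batch", celltype_col="celltype")
    assert ds.n_genes == 3 and ds.n_cells == 4
    assert len(ds.batches) == 2
    np.testing.assert_array_equal(ds.counts, tiny_counts_dataset.counts)
    np.testing.assert_array_equal(ds.gene_ids, tiny_counts_dataset.gene_ids)


def test_h5ad_equivalence(tiny_counts_dataset, tmp_path):
    save_h5ad(tiny_counts_dataset, tmp_path / "d.h5ad")
    ds = load_dataset(tmp_path / "d.h5ad", batch_col="batch", celltype_col="celltype")
    np.testing.assert_array_equal(ds.counts, tiny_counts_dataset.counts)
    np.testing.assert_array_equal(ds.batch, tiny_counts_dataset.batch)


def test_missing_batch_column_names_column(tiny_counts_dataset, tmp_path):
    save_mtx(tiny_counts_dataset, tmp_path / "mtx")
    with pytest.raises(KeyError, match="nosuch"):
        load_dataset(tmp_path / "mtx", batch_col="nosuch")


def test_non_integer_counts_rejected(tmp_path):
    table = pd.DataFrame([[0.5, 1.0]], index=["g1"], columns=["c1", "c2"])
    table.to_csv(tmp_path / "m.csv")
    meta = pd.DataFrame({"batch": ["a", "b"]})
    meta.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="integer"):
        load_dataset(tmp_path / "m.csv", metadata=tmp_path / "meta.tsv")


def test_dense_csv_loader(tmp_path):
    table = pd.DataFrame([[1, 2], [3, 4]], index=["g1", "g2"], columns=["c1", "c2"])
    table.to_csv(tmp_path / "m.csv")
    meta = pd.DataFrame({"batch": ["a", "b"]})
    meta.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
    ds = load_dataset(tmp_path / "m.csv", metadata=tmp_path / "meta.tsv")
    np.testing.assert_array_equal(ds.counts, [[1, 2], [3, 4]])


def test_dimension_mismatch_rejected(tmp_path, tiny_counts_dataset):
    save_mtx(tiny_counts_dataset, tmp_path / "mtx")
    # truncate the metadata
    pd.read_csv(tmp_path / "mtx" / "metadata.tsv", sep="\t").iloc[:2].to_csv(
        tmp_path / "mtx" / "metadata.tsv", sep="\t", index=False
    )
    with pytest.raises(ValueError, match="metadata"):
        load_dataset(tmp_path / "mtx")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _uniform_dataset(n_cells=101, n_genes=30, count=5):
    counts = np.full((n_genes, n_cells), count)
    return CellDataset(counts=counts, batch=np.array(["a"] * n_cells))


def test_qc_removes_total_count_outlier():
    ds = _uniform_dataset()
    ds.counts[:, 0] *= 100  # 100x library size; MAD of totals is 0
    out = qc_filter(ds, nmads=2.5, min_cells_per_gene=0)
    assert out.n_cells == 100
    assert "cell0" not in out.cell_ids


def test_qc_min_cells_per_gene():
    ds = _uniform_dataset(n_cells=100)
    ds.counts[0, 19:] = 0  # gene detected in exactly 19 cells
    out = qc_filter(ds, nmads=np.inf, min_cells_per_gene=20)
    assert out.n_genes == 29
    assert "gene0" not in out.gene_ids


def test_qc_identity_with_loose_thresholds(tiny_counts_dataset):
    out = qc_filter(tiny_counts_dataset, nmads=np.inf, min_cells_per_gene=0)
    np.testing.assert_array_equal(out.counts, tiny_counts_dataset.counts)


def test_qc_mito_fraction_outlier():
    ds = _uniform_dataset()
    ds.gene_ids = np.array([("MT-g" if i == 0 else "g") + str(i) for i in range(30)])
    ds.counts[0, :] = 5
    ds.counts[0, 3] = 200  # mito-heavy cell
    ds.counts[1, 3] = 0  # keep its total comparable? totals differ but mito frac dominates
    out = qc_filter(ds, nmads=2.5, min_cells_per_gene=0)
    assert "cell3" not in out.cell_ids


def test_qc_all_cells_removed_errors():
    # totals 1 and 3: with an even cell count both deviate from the median
    counts = np.array([[1, 0], [0, 3]])
    ds = CellDataset(counts=counts, batch=np.array(["a", "a"]))
    with pytest.raises(ValueError, match="nmads"):
        qc_filter(ds, nmads=0.0, min_cells_per_gene=0)


def test_qc_idempotent_on_clean_data():
    rng = np.random.default_rng(1)
    counts = rng.poisson(5, size=(40, 200))
    ds = CellDataset(counts=counts, batch=np.array(["a"] * 200))
    once = qc_filter(ds, nmads=5.0, min_cells_per_gene=5)
    twice = qc_filter(once, nmads=5.0, min_cells_per_gene=5)
    np.testing.assert_array_equal(once.counts, twice.counts)


# ---------------------------------------------------------------------------
# normalization / HVG / PCA
# ---------------------------------------------------------------------------


def test_normalize_zero_gene_row():
    ds = CellDataset(counts=np.array([[0, 0], [4, 4]]), batch=np.array(["a", "b"]))
    out = normalize_log(ds)
    np.testing.assert_array_equal(out.logexpr[0], [0.0, 0.0])


def test_normalize_equal_libraries_arithmetic():
    ds = CellDataset(counts=np.array([[3, 3], [1, 1]]), batch=np.array(["a", "b"]))
    out = normalize_log(ds)
    assert out.logexpr[0, 0] == pytest.approx(np.log2(4.0))


def test_normalize_size_factors():
    from batchmix.data import size_factors

    ds = CellDataset(counts=np.array([[100, 200]]), batch=np.array(["a", "b"]))
    np.testing.assert_allclose(size_factors(ds), [2 / 3, 4 / 3])


def test_normalize_zero_total_cell_errors():
    ds = CellDataset(counts=np.array([[0, 1]]), batch=np.array(["a", "b"]))
    with pytest.raises(ValueError, match="zero total"):
        normalize_log(ds)


def test_normalize_idempotent_shape(tiny_counts_dataset):
    once = normalize_log(tiny_counts_dataset)
    twice = normalize_log(once)
    np.testing.assert_array_equal(once.logexpr, twice.logexpr)


def test_hvg_selects_variable_gene():
    logexpr = np.vstack([np.ones(5), [0, 1, 2, 3, 4], np.full(5, 2.0)])
    ds = CellDataset(logexpr=logexpr, batch=np.array(["a"] * 5))
    assert select_hvg(ds, 1)[0] == 1


def test_hvg_full_is_permutation():
    rng = np.random.default_rng(0)
    ds = CellDataset(logexpr=rng.normal(size=(7, 9)), batch=np.array(["a"] * 9))
    assert sorted(select_hvg(ds, 7)) == list(range(7))


def test_hvg_variance_order():
    logexpr = np.vstack([[0, 2, 0, 2], [0, 4, 0, 4]])  # variances 4/3 and 16/3
    ds = CellDataset(logexpr=logexpr, batch=np.array(["a"] * 4))
    assert select_hvg(ds, 1)[0] == 1
    np.testing.assert_array_equal(select_hvg(ds, 2), [1, 0])


def test_hvg_ties_broken_by_index():
    logexpr = np.vstack([[0, 1.0], [0, 1.0], [0, 1.0]])
    ds = CellDataset(logexpr=logexpr, batch=np.array(["a", "a"]))
    np.testing.assert_array_equal(select_hvg(ds, 3), [0, 1, 2])


def test_pca_rank2_variance():
    rng = np.random.default_rng(2)
    basis = rng.normal(size=(2, 20))
    coords = rng.normal(size=(50, 2))
    ds = CellDataset(logexpr=(coords @ basis).T, batch=np.array(["a"] * 50))
    _, var = compute_pca(ds, 2)
    assert var.sum() == pytest.approx(1.0, abs=1e-8)


def test_pca_deterministic():
    rng = np.random.default_rng(3)
    ds = CellDataset(logexpr=rng.normal(size=(30, 40)), batch=np.array(["a"] * 40))
    e1, v1 = compute_pca(ds, 5)
    e2, v2 = compute_pca(ds, 5)
    np.testing.assert_array_equal(e1, e2)
    np.testing.assert_array_equal(v1, v2)


def test_pca_reconstruction_matches_eigenvalues():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(200, 50))  # cells x genes
    ds = CellDataset(logexpr=X.T, batch=np.array(["a"] * 200))
    k = 10
    scores, _ = compute_pca(ds, k)
    Xc = X - X.mean(axis=0)
    # eigendecomposition oracle on the covariance-scale Gram matrix
    eigvals = np.linalg.eigvalsh(Xc.T @ Xc)[::-1]
    recon_error = (Xc**2).sum() - (scores**2).sum()
    assert recon_error == pytest.approx(eigvals[k:].sum(), rel=1e-10)


def test_pca_var_explained_monotone_and_bounded():
    rng = np.random.default_rng(5)
    ds = CellDataset(logexpr=rng.normal(size=(30, 60)), batch=np.array(["a"] * 60))
    _, var = compute_pca(ds, 8)
    assert np.all(np.diff(var) <= 1e-12)
    assert var.sum() <= 1 + 1e-12


def test_pca_too_many_components_errors():
    ds = CellDataset(logexpr=np.zeros((3, 4)), batch=np.array(["a"] * 4))
    with pytest.raises(ValueError):
        compute_pca(ds, 5)


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------


def test_knn_collinear_points():
    graph = knn_search(np.array([[0.0], [1.0], [3.0]]), 1)
    np.testing.assert_array_equal(graph.indices[:, 0], [1, 0, 1])


def test_knn_duplicates_self_excluded():
    graph = knn_search(np.array([[1.0, 1.0]] * 4), 2)
    for c in range(4):
        assert c not in graph.indices[c]
    np.testing.assert_array_equal(graph.distances, 0.0)


def test_knn_ties_broken_by_index():
    # cells 1 and 2 equidistant from 0
    graph = knn_search(np.array([[0.0], [1.0], [-1.0], [5.0]]), 2)
    np.testing.assert_array_equal(graph.indices[0], [1, 2])


def test_knn_k_too_large_errors():
    with pytest.raises(ValueError, match="smaller"):
        knn_search(np.zeros((3, 2)), 3)


def _brute_force_knn(X, k):
    """Independent O(n^2) oracle using python sorting."""
    n = len(X)
    idx = np.empty((n, k), dtype=int)
    dist = np.empty((n, k))
    for i in range(n):
        pairs = sorted(
            (float(np.sqrt(((X[i] - X[j]) ** 2).sum())), j) for j in range(n) if j != i
        )
        idx[i] = [j for _, j in pairs[:k]]
        dist[i] = [d for d, _ in pairs[:k]]
    return idx, dist


def test_knn_matches_brute_force_oracle():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(500, 5))
    graph = knn_search(X, 10)
    idx, dist = _brute_force_knn(X, 10)
    np.testing.assert_array_equal(graph.indices, idx)
    np.testing.assert_allclose(graph.distances, dist, rtol=1e-10)


def test_knn_rows_sorted(mixed_embedding):
    graph = knn_search(mixed_embedding.embedding, 20)
    assert np.all(np.diff(graph.distances, axis=1) >= 0)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def test_permute_zero_fraction_identity(rng):
    batch = np.array(["a", "b", "c"] * 10)
    np.testing.assert_array_equal(permute_batch_labels(batch, 0.0, 1), batch)


def test_permute_full_preserves_multiset():
    batch = np.array(["a"] * 30 + ["b"] * 10)
    out = permute_batch_labels(batch, 1.0, 2)
    assert sorted(out) == sorted(batch)
    assert not np.array_equal(out, batch)  # randomized order


def test_permute_selects_expected_count():
    batch = np.array(list("aabbbabbba"))
    # replicate the seeded draws: 5 positions then a permutation of them
    ref = np.random.default_rng(5)
    pos = ref.choice(10, size=5, replace=False)
    perm = ref.permutation(5)
    expected = batch.copy()
    expected[pos] = expected[pos][perm]
    np.testing.assert_array_equal(permute_batch_labels(batch, 0.5, 5), expected)


@pytest.mark.parametrize("fraction", [0.0, 0.2, 0.5, 0.8, 1.0])
def test_permute_preserves_frequencies(fraction):
    rng = np.random.default_rng(9)
    batch = rng.choice(["a", "b", "c"], size=97, p=[0.5, 0.3, 0.2])
    out = permute_batch_labels(batch, fraction, 4)
    for lv in "abc":
        assert (out == lv).sum() == (batch == lv).sum()


def test_downsample_zero_fraction_unchanged(tiny_counts_dataset):
    out = downsample_batch(tiny_counts_dataset, "t1", "a", 0.0, 1)
    np.testing.assert_array_equal(out.counts, tiny_counts_dataset.counts)


def test_downsample_full_empties_stratum():
    rng = np.random.default_rng(1)
    n = 80
    ds = CellDataset(
        counts=rng.poisson(5, size=(10, n)),
        batch=np.array(["a", "b"] * (n // 2)),
        celltype=np.array(["t1"] * (n // 2) + ["t2"] * (n // 2)),
    )
    out = downsample_batch(ds, "t1", "a", 1.0, 1)
    assert not np.any((out.celltype == "t1") & (out.batch == "a"))
    assert np.any((out.celltype == "t1") & (out.batch == "b"))


def test_downsample_half_of_forty():
    ds = CellDataset(
        counts=np.ones((2, 60), dtype=int),
        batch=np.array(["a"] * 40 + ["b"] * 20),
        celltype=np.array(["t"] * 60),
    )
    out = downsample_batch(ds, "t", "a", 0.5, 3)
    assert out.n_cells == 40
    assert (out.batch == "a").sum() == 20


def test_downsample_missing_stratum_errors(tiny_counts_dataset):
    with pytest.raises(ValueError, match="empty"):
        downsample_batch(tiny_counts_dataset, "t1", "zzz", 0.5, 1)


# ---------------------------------------------------------------------------
# params / containers
# ---------------------------------------------------------------------------


def test_metric_params_validation():
    with pytest.raises(ValueError):
        MetricParams(k=0)
    with pytest.raises(ValueError):
        MetricParams(k=10, k_min=20)
    with pytest.raises(ValueError):
        MetricParams(k_pos=500)


def test_dataset_shape_validation():
    with pytest.raises(ValueError, match="batch"):
        CellDataset(counts=np.ones((2, 3), dtype=int), batch=np.array(["a", "b"]))
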