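"""Per-cell batch-mixing scores.

All metrics here score each cell from the batch composition and/or distance
structure of its k-nearest neighbourhood in a low-dimensional embedding:

* ``cms`` -- p-value of a k-sample Anderson-Darling test comparing the
  batch-wise distance distributions within the neighbourhood (variants with
  a density-adaptive neighbourhood and a per-batch minimum neighbourhood).
* ``simpson_index`` -- inverse Simpson index of the (optionally weighted)
  neighbourhood batch probabilities: the effective number of batches.
* ``entropy`` -- normalized Shannon entropy of the neighbourhood batch
  fractions.
* ``mixing_metric`` -- median neighbour rank at which each batch's
  ``k_pos``-th representative appears (low = well mixed).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde

from .adtest import ad_ksample
from .data import MetricParams, NeighborGraph
from .results import MetricResult, make_cell_result

__all__ = [
    "cms",
    "find_kmin",
    "extend_bmin",
    "simpson_index",
    "entropy",
    "mixing_metric",
]


# ---------------------------------------------------------------------------
# cms
# ---------------------------------------------------------------------------


def _cms_score(dist: np.ndarray, nb_batch: np.ndarray) -> float:
    """AD p-value for one neighbourhood; batches with < 2 neighbours dropped."""
    groups = [dist[nb_batch == b] for b in np.unique(nb_batch)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        return 0.0  # neighbourhood dominated by one batch: maximal bias
    return ad_ksample(groups).pvalue


def find_kmin(dist: np.ndarray, k_min: int) -> int:
    """Density-adaptive neighbourhood size.

    Smooths the neighbour-distance density (Gaussian KDE, Silverman
    bandwidth, 512-point grid over [0, max distance]) and returns the number
    of neighbours closer than the first local minimum after the global mode,
    floored at ``k_min`` and capped at ``len(dist)``.  With no interior
    minimum (unimodal profile) the full neighbourhood is kept.
    """
    dist = np.asarray(dist, dtype=float)
    k = len(dist)
    if k < 3 or np.allclose(dist, dist[0]):
        return k
    try:
        kde = gaussian_kde(dist, bw_method="silverman")
    except np.linalg.LinAlgError:
        return k
    grid = np.linspace(0.0, dist.max(), 512)
    dens = kde(grid)
    # mode = first local maximum of the smoothed density (equals the global
    # mode for unimodal profiles; robust when well-separated modes tie)
    rises = np.flatnonzero(np.diff(dens) < 0)
    mode = int(rises[0]) if rises.size else 511
    cut = None
    for i in range(mode + 1, 512):
        if dens[i] > dens[i - 1]:
            cut = grid[i - 1]
            break
    if cut is None:
        return k
    eff = int(np.sum(dist < cut))
    return min(max(eff, k_min), k)


def extend_bmin(
    embedding: np.ndarray, batch: np.ndarray, cell: int, b_min: int
) -> np.ndarray:
    """Distance-ordered neighbour list extended to >= b_min cells per batch.

    Walks outward from ``cell`` (ties broken by cell index, self excluded)
    until every batch level contributes at least ``b_min`` neighbours.
    """
    batch = np.asarray(batch)
    levels, counts = np.unique(batch, return_counts=True)
    adj = counts - (batch[cell] == levels)  # cell itself is not a neighbour
    short = levels[adj < b_min]
    if short.size:
        raise ValueError(f"batch {short[0]!r} has fewer than b_min={b_min} cells")
    d = np.sqrt(((embedding - embedding[cell]) ** 2).sum(axis=1))
    d[cell] = np.inf
    order = np.argsort(d, kind="stable")[:-1]  # drop self (inf sorts last)
    codes = np.searchsorted(levels, batch[order])
    seen = np.zeros(len(levels), dtype=int)
    for pos, c in enumerate(codes):
        seen[c] += 1
        if seen.min() >= b_min:
            return order[: pos + 1]
    raise AssertionError("unreachable: global counts checked above")


def cms(
    graph: NeighborGraph,
    batch: np.ndarray,
    variant: str = "default",
    params: MetricParams | None = None,
    embedding: np.ndarray | None = None,
) -> MetricResult:
    """Cell-specific mixing score.

    For each cell the neighbour distances are partitioned by neighbour batch
    and compared with a k-sample Anderson-Darling test; the score is the
    test's p-value (high = well mixed).  Batches contributing fewer than two
    neighbours are dropped; if fewer than two batches remain the score is 0.

    ``variant='kmin'`` restricts each neighbourhood to the cells before the
    first local minimum of its distance density (>= ``params.k_min``);
    ``variant='bmin'`` extends it until every batch has >= ``params.b_min``
    cells (requires ``embedding``).
    """
    params = params or MetricParams()
    batch = np.asarray(batch)
    if len(np.unique(batch)) < 2:
        raise ValueError("cms requires at least 2 batches")
    n = graph.n_cells
    scores = np.empty(n)
    if variant in ("default", "kmin"):
        nb_batch_all = batch[graph.indices]
        for c in range(n):
            dist = graph.distances[c]
            nb_batch = nb_batch_all[c]
            if variant == "kmin":
                eff = find_kmin(dist, params.k_min)
                dist, nb_batch = dist[:eff], nb_batch[:eff]
            scores[c] = _cms_score(dist, nb_batch)
    elif variant == "bmin":
        if embedding is None:
            raise ValueError("variant='bmin' requires the embedding")
        for c in range(n):
            nbrs = extend_bmin(embedding, batch, c, params.b_min)
            dist = np.sqrt(((embedding[nbrs] - embedding[c]) ** 2).sum(axis=1))
            scores[c] = _cms_score(dist, batch[nbrs])
    else:
        raise ValueError(f"unknown cms variant {variant!r}")
    name = "cms" if variant == "default" else f"cms_{variant}"
    return make_cell_result(name, scores, {"k": graph.k, "variant": variant})


# ---------------------------------------------------------------------------
# inverse Simpson index family
# ---------------------------------------------------------------------------


def _calibrated_weights(d: np.ndarray, perplexity: float, tol: float = 1e-5) -> np.ndarray:
    """Gaussian kernel weights with entropy log(perplexity), via bisection.

    Weights ``w_i ~ exp(-beta * d_i^2)`` with per-cell ``beta`` chosen so the
    Shannon entropy of ``w`` equals ``log(perplexity)`` (natural log), as in
    perplexity-calibrated t-SNE/LISI neighbourhoods.
    """
    d2 = d.astype(float) ** 2
    d2 = d2 - d2.min()
    target = np.log(perplexity)

    def entropy_of(beta):
        w = np.exp(-beta * d2)
        s = w.sum()
        if s <= 0:
            return 0.0, w
        w /= s
        nz = w > 0
        return float(-(w[nz] * np.log(w[nz])).sum()), w

    lo, hi = 0.0, 1.0
    h, w = entropy_of(hi)
    it = 0
    while h > target and it < 100:  # increase beta until entropy below target
        hi *= 2.0
        h, w = entropy_of(hi)
        it += 1
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        h, w = entropy_of(mid)
        if abs(h - target) < tol:
            break
        if h > target:
            lo = mid
        else:
            hi = mid
    return w


def simpson_index(
    graph: NeighborGraph,
    batch: np.ndarray,
    weighting: str = "none",
    params: MetricParams | None = None,
) -> MetricResult:
    """Inverse Simpson index of neighbourhood batch probabilities.

    ``score = 1 / sum_b p(b)^2`` where ``p(b)`` is the total (normalized)
    neighbour weight of batch ``b``.  ``weighting``:

    * ``"none"`` (isi) -- uniform weights over the k neighbours;
    * ``"inverse_square"`` (wisi) -- ``w ~ 1 / (d^2 + eps)`` with
      ``eps = machine-eps * median(d)^2`` (duplicates dominate, never divide
      by zero);
    * ``"gaussian"`` (lisi) -- per-cell Gaussian kernel calibrated so the
      weight entropy equals log(perplexity), over the nearest
      ``3 * perplexity`` neighbours.

    A single-batch dataset gives all scores exactly 1.
    """
    params = params or MetricParams()
    batch = np.asarray(batch)
    levels = np.unique(batch)
    codes = np.searchsorted(levels, batch)
    nb_codes = codes[graph.indices]
    n, k = graph.indices.shape
    B = len(levels)
    scores = np.empty(n)
    if weighting == "none":
        counts = np.stack([(nb_codes == b).sum(axis=1) for b in range(B)], axis=1)
        p = counts / k
        scores = 1.0 / (p**2).sum(axis=1)
    elif weighting == "inverse_square":
        eps_mach = np.finfo(float).eps
        for c in range(n):
            d = graph.distances[c]
            eps = eps_mach * max(np.median(d) ** 2, eps_mach)
            w = 1.0 / (d**2 + eps)
            w /= w.sum()
            p = np.bincount(nb_codes[c], weights=w, minlength=B)
            scores[c] = 1.0 / (p**2).sum()
    elif weighting == "gaussian":
        m = min(3 * params.perplexity, k)
        for c in range(n):
            w = _calibrated_weights(graph.distances[c, :m], params.perplexity)
            p = np.bincount(nb_codes[c, :m], weights=w, minlength=B)
            scores[c] = 1.0 / (p**2).sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    name = {"none": "isi", "inverse_square": "wisi", "gaussian": "lisi"}[weighting]
    return make_cell_result(name, scores, {"k": graph.k, "weighting": weighting})


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------


def entropy(
    graph: NeighborGraph,
    batch: np.ndarray,
    params: MetricParams | None = None,
    normalization: str = "log_batches",
) -> MetricResult:
    """Normalized Shannon entropy of neighbourhood batch fractions.

    ``H = -sum_b p(b) log2 p(b)`` with ``0 log 0 := 0``.  The default
    normalization divides by ``log2(B)`` (B = number of batch levels in the
    dataset) so a uniform neighbourhood scores exactly 1;
    ``normalization="n_batches"`` divides by ``B`` instead (the printed
    formula variant, which does not reach 1).  Single-batch data scores 0.
    """
    params = params or MetricParams()
    batch = np.asarray(batch)
    levels = np.unique(batch)
    B = len(levels)
    codes = np.searchsorted(levels, batch)
    nb_codes = codes[graph.indices]
    k = graph.indices.shape[1]
    counts = np.stack([(nb_codes == b).sum(axis=1) for b in range(B)], axis=1)
    p = counts / k
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    H = -terms.sum(axis=1)
    if B < 2:
        scores = np.zeros(graph.n_cells)
    elif normalization == "log_batches":
        scores = H / np.log2(B)
    elif normalization == "n_batches":
        scores = H / B
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return make_cell_result("entropy", scores, {"k": graph.k, "normalization": normalization})


# ---------------------------------------------------------------------------
# mixing metric
# ---------------------------------------------------------------------------


def mixing_metric(
    graph: NeighborGraph,
    batch: np.ndarray,
    params: MetricParams | None = None,
) -> MetricResult:
    """Median neighbour rank of each batch's ``k_pos``-th representative.

    For each cell and each batch level, the 1-based position within the
    distance-ordered neighbour list at which that batch's ``k_pos``-th cell
    appears (or ``k_mm`` if the batch contributes fewer than ``k_pos``
    neighbours); the score is the median of these ranks over batches.
    Low = well mixed.  The graph should be built with ``k = params.k_mm``.
    """
    params = params or MetricParams()
    batch = np.asarray(batch)
    levels = np.unique(batch)
    codes = np.searchsorted(levels, batch)
    nb_codes = codes[graph.indices]
    n, k = nb_codes.shape
    k_pos, cap = params.k_pos, params.k_mm
    ranks = np.full((n, len(levels)), float(cap))
    for b in range(len(levels)):
        is_b = nb_codes == b
        cum = np.cumsum(is_b, axis=1)
        hit = cum >= k_pos
        has = hit[:, -1]
        ranks[has, b] = np.argmax(hit[has], axis=1) + 1  # 1-based rank
    scores = np.median(ranks, axis=1)
    return make_cell_result("mm", scores, {"k_mm": cap, "k_pos": k_pos})
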