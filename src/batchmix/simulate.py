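"""Negative-binomial count simulation with tunable, cell-type-specific batch
effects, plus the batch-characterization statistics (variance partitioning
and batch logFC / DE estimation).

Counts are drawn as ``Y ~ NB(mu, phi)`` with ``Var = mu + phi * mu^2`` and

    mu[g, c] = exp(beta0[g, t_c]) * lambda_c * 2 ** (lfc[g, t_c, b_c] * theta)

where ``beta0`` is the per-(gene, cell type) baseline (natural log scale),
``lambda_c`` a cell size factor, ``lfc`` the per-(gene, cell type, batch)
batch log2 fold change (0 for the reference batch) and ``theta >= 0`` a
global multiplier of the batch effect: ``theta = 0`` is batch-free,
``theta = 1`` reproduces the reference strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import CellDataset, normalize_log, size_factors

__all__ = [
    "SimulationParameters",
    "VariancePartition",
    "BatchLogFCTable",
    "estimate_params",
    "simulate_counts",
    "simulate_series",
    "variance_partition",
    "estimate_batch_logfc",
    "DEFAULT_THETA_GRID",
]

#: default 13-point grid of batch-strength multipliers spanning [0, 4]
DEFAULT_THETA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class SimulationParameters:
    """Estimated or constructed NB simulation parameters.

    ``phi``: per-gene dispersion (> 0); ``beta0``: genes x cell-types
    baseline (natural log); ``lfc``: genes x cell-types x batches log2 batch
    fold changes, identically 0 for the reference batch (index 0);
    ``size_factors``: per-reference-cell effective library size factors
    (mean 1); ``celltype_props`` / ``batch_props``: sampling probabilities.
    """

    phi: np.ndarray
    beta0: np.ndarray
    lfc: np.ndarray
    size_factors: np.ndarray
    celltype_props: np.ndarray
    batch_props: np.ndarray
    celltype_levels: np.ndarray = field(default=None)
    batch_levels: np.ndarray = field(default=None)
    gene_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.lfc = np.asarray(self.lfc, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.celltype_props = np.asarray(self.celltype_props, dtype=float)
        self.batch_props = np.asarray(self.batch_props, dtype=float)
        G, T = self.beta0.shape
        if self.lfc.shape != (G, T, len(self.batch_props)):
            raise ValueError("lfc must be genes x cell types x batches")
        if np.any(self.phi <= 0) or np.any(self.size_factors <= 0):
            raise ValueError("phi and size factors must be positive")
        if np.any(self.lfc[:, :, 0] != 0):
            raise ValueError("reference-batch logFCs must be 0")
        for p in (self.celltype_props, self.batch_props):
            if not np.isclose(p.sum(), 1.0):
                raise ValueError("sampling proportions must sum to 1")
        if self.celltype_levels is None:
            self.celltype_levels = np.array([f"ct{i}" for i in range(T)])
        if self.batch_levels is None:
            self.batch_levels = np.array([f"batch{i}" for i in range(len(self.batch_props))])
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene{i}" for i in range(G)])


@dataclass
class VariancePartition:
    """Per-gene variance components and PVE shares.

    Components: cell type (``var_celltype``), batch (``var_batch``),
    interaction (``var_interaction``) and residual (``var_residual``), all
    >= 0.  ``pve_*`` are the component shares of the per-gene total (they sum
    to 1); a constant gene is assigned residual share 1 by convention.
    ``converged`` flags genes where the REML fit converged (otherwise a
    non-negative method-of-moments estimate is used).
    """

    var_celltype: np.ndarray
    var_batch: np.ndarray
    var_interaction: np.ndarray
    var_residual: np.ndarray
    converged: np.ndarray

    @property
    def totals(self) -> np.ndarray:
        return self.var_celltype + self.var_batch + self.var_interaction + self.var_residual

    def _share(self, comp: np.ndarray) -> np.ndarray:
        tot = self.totals
        return np.where(tot > 0, comp / np.where(tot > 0, tot, 1.0), 0.0)

    @property
    def pve_celltype(self) -> np.ndarray:
        return self._share(self.var_celltype)

    @property
    def pve_batch(self) -> np.ndarray:
        return self._share(self.var_batch)

    @property
    def pve_interaction(self) -> np.ndarray:
        return self._share(self.var_interaction)

    @property
    def pve_residual(self) -> np.ndarray:
        tot = self.totals
        return np.where(tot > 0, self._share(self.var_residual), 1.0)


@dataclass
class BatchLogFCTable:
    """Per-(gene, cell type) batch logFCs, p-values and DE calls.

    ``logfc[pair]`` is a genes x cell-types matrix of log2 fold changes for
    one batch pair; ``padj`` the BH-adjusted Welch p-values (adjusted per
    cell type); DE flag at adjusted p <= 0.05.  ``summaries`` carries the
    dataset-level statistics: DE proportion, mean between-cell-type Pearson
    correlation of logFC vectors and mean DE-gene overlap.
    """

    pairs: list
    logfc: dict
    pvalue: dict
    padj: dict
    de: dict
    summaries: dict


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------


def estimate_params(
    ref: CellDataset,
    reference_batch: object | None = None,
    pseudocount: float = 1.0,
    beta0_floor: float = 1e-3,
) -> SimulationParameters:
    """Estimate NB simulation parameters from a reference dataset.

    * ``lambda_c`` = library size / mean library size;
    * ``beta0[g, t]`` = log of the size-factor-normalized mean count of gene
      ``g`` in cell type ``t`` within the reference batch, floored at
      ``beta0_floor``;
    * ``lfc[g, t, b]`` = log2 ratio of normalized stratum means versus the
      reference batch, shrunk with ``pseudocount`` normalized counts (set to
      0, with a warning, where a stratum mean is exactly 0);
    * ``phi_g`` by method of moments on normalized counts pooled *within*
      (cell type, batch) strata (removes between-stratum mean variance), then
      combined across strata by a df-weighted mean and floored at 1e-4.
    """
    if ref.celltype is None:
        raise ValueError("reference dataset needs cell-type labels")
    lam = size_factors(ref)
    norm = ref.counts / lam  # genes x cells
    ct_levels = np.unique(ref.celltype)
    b_levels = np.unique(ref.batch)
    if reference_batch is None:
        reference_batch = b_levels[0]
    b_levels = np.concatenate([[reference_batch], b_levels[b_levels != reference_batch]])
    G, T, B = ref.n_genes, len(ct_levels), len(b_levels)

    means = np.zeros((G, T, B))
    phi_num = np.zeros(G)
    phi_den = 0.0
    for t, ct in enumerate(ct_levels):
        for b, bt in enumerate(b_levels):
            idx = np.flatnonzero((ref.celltype == ct) & (ref.batch == bt))
            if idx.size == 0:
                continue
            sub = norm[:, idx]
            m = sub.mean(axis=1)
            means[:, t, b] = m
            if idx.size >= 2:
                s2 = sub.var(axis=1, ddof=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    phi_s = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-12) ** 2, 0.0)
                phi_num += (idx.size - 1) * phi_s
                phi_den += idx.size - 1
    phi = np.maximum(phi_num / max(phi_den, 1.0), 1e-4)

    beta0 = np.log(np.maximum(means[:, :, 0], beta0_floor))
    lfc = np.log2((means + pseudocount) / (means[:, :, [0]] + pseudocount))
    zero = (means == 0) | (means[:, :, [0]] == 0)
    if np.any(zero[:, :, 1:]):
        warnings.warn("all-zero strata encountered; their logFCs were set to 0")
        lfc[zero] = 0.0
    lfc[:, :, 0] = 0.0

    ct_props = np.array([(ref.celltype == ct).mean() for ct in ct_levels])
    b_props = np.array([(ref.batch == bt).mean() for bt in b_levels])
    return SimulationParameters(
        phi=phi,
        beta0=beta0,
        lfc=lfc,
        size_factors=lam,
        celltype_props=ct_props,
        batch_props=b_props,
        celltype_levels=ct_levels,
        batch_levels=b_levels,
        gene_ids=ref.gene_ids,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _draw_assignments(params: SimulationParameters, n_cells: int, rng: np.random.Generator):
    t_idx = rng.choice(len(params.celltype_props), size=n_cells, p=params.celltype_props)
    b_idx = rng.choice(len(params.batch_props), size=n_cells, p=params.batch_props)
    lam = rng.choice(params.size_factors, size=n_cells, replace=True)
    return t_idx, b_idx, lam


def simulate_counts(
    params: SimulationParameters,
    theta: float,
    n_cells: int,
    seed: int,
    _assignments=None,
) -> CellDataset:
    """Simulate an NB count dataset with batch strength ``theta``.

    Each cell is assigned a (cell type, batch) pair and a size factor drawn
    from the reference (seeded); counts are then sampled gene-wise from
    ``NB(exp(beta0) * lambda * 2^(lfc * theta), phi)``.  Fully reproducible
    from ``seed``.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    if _assignments is None:
        t_idx, b_idx, lam = _draw_assignments(params, n_cells, rng)
    else:
        t_idx, b_idx, lam = _assignments
    mu = np.exp(params.beta0[:, t_idx]) * lam[None, :] * 2.0 ** (
        params.lfc[np.arange(len(params.phi))[:, None], t_idx[None, :], b_idx[None, :]] * theta
    )
    r = 1.0 / params.phi  # NB "size"
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p).astype(np.int64)
    return CellDataset(
        counts=counts,
        batch=params.batch_levels[b_idx],
        celltype=params.celltype_levels[t_idx],
        gene_ids=params.gene_ids,
    )


def simulate_series(
    params: SimulationParameters,
    thetas=DEFAULT_THETA_GRID,
    n_cells: int = 2000,
    seed: int = 0,
) -> list[CellDataset]:
    """One dataset per theta, sharing cell assignments across the series.

    The (cell type, batch, size factor) assignments are drawn once from
    ``seed``, so datasets in a series differ only through the counts drawn at
    each theta (per-theta derived seeds).
    """
    thetas = list(thetas)
    if not thetas or min(thetas) < 0:
        raise ValueError("thetas must be non-empty and >= 0")
    rng = np.random.default_rng(seed)
    assign = _draw_assignments(params, n_cells, rng)
    children = np.random.SeedSequence(seed).spawn(len(thetas))
    out = []
    for theta, child in zip(thetas, children):
        counts_seed = child.generate_state(1)[0]
        out.append(simulate_counts(params, theta, n_cells, int(counts_seed), _assignments=assign))
    return out


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------


def _reml_loglik(logv: np.ndarray, ybar, n_s, t_of_s, b_of_s, sse, N, S) -> float:
    """Negative restricted log-likelihood of the crossed random-effects model,
    written on collapsed (cell type, batch) stratum means."""
    vp, vb, vpb, ve = np.exp(logv)
    V = (
        vp * (t_of_s[:, None] == t_of_s[None, :])
        + vb * (b_of_s[:, None] == b_of_s[None, :])
        + np.diag(np.full(S, vpb) + ve / n_s)
    )
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ones = np.ones(S)
    Vi_y = np.linalg.solve(V, ybar)
    Vi_1 = np.linalg.solve(V, ones)
    denom = ones @ Vi_1
    mu = (ones @ Vi_y) / denom
    r = ybar - mu
    quad = r @ np.linalg.solve(V, r)
    ll_means = -0.5 * (logdet + np.log(denom) + quad)
    ll_within = -0.5 * ((N - S) * np.log(ve) + sse / ve) if N > S else 0.0
    return -(ll_means + ll_within)


def _mom_components(ybar, n_s, t_of_s, b_of_s, sse, N, S):
    """Non-negative method-of-moments fallback on stratum means."""
    ve = sse / max(N - S, 1)
    t_levels = np.unique(t_of_s)
    b_levels = np.unique(b_of_s)
    t_means = np.array([ybar[t_of_s == t].mean() for t in t_levels])
    b_means = np.array([ybar[b_of_s == b].mean() for b in b_levels])
    grand = ybar.mean()
    inter = ybar - t_means[np.searchsorted(t_levels, t_of_s)] - b_means[
        np.searchsorted(b_levels, b_of_s)
    ] + grand
    noise = ve * np.mean(1.0 / n_s)
    vp = max(np.var(t_means, ddof=1) - noise / len(b_levels), 0.0) if len(t_levels) > 1 else 0.0
    vb = max(np.var(b_means, ddof=1) - noise / len(t_levels), 0.0) if len(b_levels) > 1 else 0.0
    vpb = max(np.var(inter, ddof=1) - noise, 0.0) if S > 2 else 0.0
    return vp, vb, vpb, ve


def variance_partition(ds: CellDataset, tol: float = 1e-6, maxiter: int = 200) -> VariancePartition:
    """Per-gene variance components of the crossed random-intercept model.

    For every gene, log-expression is modelled with random intercepts for
    cell type, batch and their interaction plus residual noise; components
    are estimated by REML (Nelder-Mead on log-variances over collapsed
    stratum sufficient statistics; floored at 0), with a non-negative
    method-of-moments fallback when the fit does not converge.
    """
    if ds.logexpr is None:
        raise ValueError("variance_partition requires logexpr")
    if ds.celltype is None:
        raise ValueError("variance_partition requires cell-type labels")
    ct = np.asarray(ds.celltype)
    bt = np.asarray(ds.batch)
    if len(np.unique(ct)) < 2 or len(np.unique(bt)) < 2:
        raise ValueError("need >= 2 cell types and >= 2 batches")
    strata, s_of_cell = np.unique(
        np.char.add(np.char.add(ct.astype(str), "\x1f"), bt.astype(str)), return_inverse=True
    )
    S = len(strata)
    n_s = np.bincount(s_of_cell).astype(float)
    first = np.array([np.flatnonzero(s_of_cell == s)[0] for s in range(S)])
    t_of_s = np.unique(ct, return_inverse=True)[1][first]
    b_of_s = np.unique(bt, return_inverse=True)[1][first]
    N = ds.n_cells
    G = ds.n_genes

    Y = ds.logexpr
    # stratum sums / sums of squares per gene
    sums = np.zeros((G, S))
    sqs = np.zeros((G, S))
    for s in range(S):
        cols = s_of_cell == s
        sums[:, s] = Y[:, cols].sum(axis=1)
        sqs[:, s] = (Y[:, cols] ** 2).sum(axis=1)
    ybars = sums / n_s
    sse_g = (sqs - sums**2 / n_s).sum(axis=1)

    vp = np.zeros(G)
    vb = np.zeros(G)
    vpb = np.zeros(G)
    ve = np.zeros(G)
    ok = np.zeros(G, dtype=bool)
    for g in range(G):
        ybar = ybars[g]
        sse = max(sse_g[g], 0.0)
        if np.ptp(Y[g]) == 0:  # constant gene: all components 0
            continue
        init = _mom_components(ybar, n_s, t_of_s, b_of_s, sse, N, S)
        x0 = np.log(np.maximum(np.array(init), 1e-6))
        res = optimize.minimize(
            _reml_loglik,
            x0,
            args=(ybar, n_s, t_of_s, b_of_s, sse, N, S),
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": maxiter * 4},
        )
        if res.success or res.fun < _reml_loglik(x0, ybar, n_s, t_of_s, b_of_s, sse, N, S):
            comps = np.exp(res.x)
            comps[comps < 1e-8] = 0.0
            vp[g], vb[g], vpb[g], ve[g] = comps
            ok[g] = bool(res.success)
        else:
            vp[g], vb[g], vpb[g], ve[g] = init
    return VariancePartition(vp, vb, vpb, ve, ok)


# ---------------------------------------------------------------------------
# batch logFC / DE estimation
# ---------------------------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def estimate_batch_logfc(
    ds: CellDataset, alpha: float = 0.05, pseudocount: float = 1.0
) -> BatchLogFCTable:
    """Batch logFCs, Welch-test p-values and DE calls per (gene, cell type).

    For each batch pair and cell type: logFC = log2 ratio of pseudocount-
    shrunk normalized stratum means; p-value from a two-sample Welch t-test
    on log-expression; BH adjustment per cell type; DE at adjusted
    p <= ``alpha``.  ``summaries`` holds the DE proportion, the mean
    between-cell-type Pearson correlation of per-gene logFC vectors and the
    mean pairwise DE-gene overlap coefficient.
    """
    if ds.celltype is None:
        raise ValueError("estimate_batch_logfc requires cell-type labels")
    if ds.logexpr is None:
        ds = normalize_log(ds)
    lam = size_factors(ds)
    norm = ds.counts / lam
    ct_levels = np.unique(ds.celltype)
    b_levels = np.unique(ds.batch)
    pairs = [(b_levels[i], b_levels[j]) for i in range(len(b_levels)) for j in range(i + 1, len(b_levels))]
    G, T = ds.n_genes, len(ct_levels)

    logfc = {pair: np.zeros((G, T)) for pair in pairs}
    pvalue = {pair: np.ones((G, T)) for pair in pairs}
    padj = {pair: np.ones((G, T)) for pair in pairs}
    de = {pair: np.zeros((G, T), dtype=bool) for pair in pairs}
    for pair in pairs:
        b1, b2 = pair
        for t, ct in enumerate(ct_levels):
            i1 = np.flatnonzero((ds.celltype == ct) & (ds.batch == b1))
            i2 = np.flatnonzero((ds.celltype == ct) & (ds.batch == b2))
            if len(i1) < 2 or len(i2) < 2:
                warnings.warn(f"stratum too small for ({ct!r}, {b1!r}/{b2!r}); p = 1")
                continue
            m1 = norm[:, i1].mean(axis=1)
            m2 = norm[:, i2].mean(axis=1)
            logfc[pair][:, t] = np.log2((m2 + pseudocount) / (m1 + pseudocount))
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_ind(
                    ds.logexpr[:, i2], ds.logexpr[:, i1], axis=1, equal_var=False
                )
            p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
            pvalue[pair][:, t] = p
            padj[pair][:, t] = _bh_adjust(p)
        de[pair] = padj[pair] <= alpha

    # dataset-level summaries (first pair family pooled)
    all_de = np.concatenate([de[p].ravel() for p in pairs])
    de_prop = float(all_de.mean())
    cors, overlaps = [], []
    for pair in pairs:
        for t1 in range(T):
            for t2 in range(t1 + 1, T):
                v1, v2 = logfc[pair][:, t1], logfc[pair][:, t2]
                if v1.std() > 0 and v2.std() > 0:
                    cors.append(float(np.corrcoef(v1, v2)[0, 1]))
                d1, d2 = de[pair][:, t1], de[pair][:, t2]
                m = min(d1.sum(), d2.sum())
                if m > 0:
                    overlaps.append(float((d1 & d2).sum() / m))
    summaries = {
        "de_proportion": de_prop,
        "lfc_correlation": float(np.mean(cors)) if cors else np.nan,
        "de_overlap": float(np.mean(overlaps)) if overlaps else np.nan,
    }
    return BatchLogFCTable(pairs, logfc, pvalue, padj, de, summaries)
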