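"""Benchmark harness: score aggregation/standardization, Spearman
correlations, the permutation / batch-strength-scaling / batch-imbalance
evaluation tasks, detection and imbalance limits, and threshold-based
categorization of metric performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .cellwise import cms, entropy, mixing_metric, simpson_index
from .data import (
    CellDataset,
    MetricParams,
    compute_pca,
    downsample_batch,
    knn_search,
    normalize_log,
    permute_batch_labels,
)
from .groupwise import asw_batch, graph_connectivity, kbet, pcr
from .results import DIRECTIONS, MetricResult
from .simulate import SimulationParameters, simulate_series

__all__ = [
    "CELL_METRICS",
    "GROUP_METRICS",
    "ALL_METRICS",
    "MetricEngine",
    "BenchmarkSeries",
    "Limit",
    "aggregate_scores",
    "standardize_scores",
    "spearman",
    "detection_limit",
    "imbalance_limit",
    "run_permutation_task",
    "run_scaling_task",
    "run_imbalance_task",
    "run_characteristics_task",
    "categorize",
    "encode_categories",
]

CELL_METRICS = ("cms", "cms_kmin", "cms_bmin", "isi", "wisi", "lisi", "entropy", "mm")
GROUP_METRICS = ("kbet", "graph", "asw", "pcr")
ALL_METRICS = CELL_METRICS + GROUP_METRICS


# ---------------------------------------------------------------------------
# scoring engine (caches label-independent structures)
# ---------------------------------------------------------------------------


class MetricEngine:
    """Scores named metrics on one dataset, caching expression-derived
    structures (embedding, kNN graphs, the PCR PCA) so that label
    perturbations can be re-scored cheaply."""

    def __init__(self, ds: CellDataset, params: MetricParams | None = None):
        self.params = params or MetricParams()
        self.ds = ds
        self._graphs: dict[int, object] = {}
        self._pcr_cache = None
        if ds.embedding is not None:
            self.embedding = ds.embedding
        else:
            if ds.logexpr is None:
                ds = normalize_log(ds)
                self.ds = ds
            n_pcs = min(self.params.n_pcs, ds.n_genes, ds.n_cells - 1)
            self.embedding, _ = compute_pca(ds, n_pcs)

    def graph(self, k: int):
        k = min(k, self.ds.n_cells - 1)
        if k not in self._graphs:
            self._graphs[k] = knn_search(self.embedding, k)
        return self._graphs[k]

    def score(
        self,
        metric: str,
        batch: np.ndarray | None = None,
        seed: int = 0,
    ) -> MetricResult:
        """Compute one metric; ``batch`` overrides the dataset's labels
        (cell types and expression stay fixed, as in the permutation task)."""
        p = self.params
        batch = self.ds.batch if batch is None else np.asarray(batch)
        if metric == "cms":
            return cms(self.graph(p.k), batch, "default", p)
        if metric == "cms_kmin":
            return cms(self.graph(p.k), batch, "kmin", p)
        if metric == "cms_bmin":
            return cms(self.graph(p.k), batch, "bmin", p, embedding=self.embedding)
        if metric == "isi":
            return simpson_index(self.graph(p.k), batch, "none", p)
        if metric == "wisi":
            return simpson_index(self.graph(p.k), batch, "inverse_square", p)
        if metric == "lisi":
            return simpson_index(self.graph(max(3 * p.perplexity, 3)), batch, "gaussian", p)
        if metric == "entropy":
            return entropy(self.graph(p.k), batch, p)
        if metric == "mm":
            return mixing_metric(self.graph(p.k_mm), batch, p)
        if metric == "kbet":
            return kbet(self.embedding, batch, self.ds.celltype, p, seed=seed)
        if metric == "graph":
            return graph_connectivity(self.embedding, self.ds.celltype, p)
        if metric == "asw":
            return asw_batch(self.embedding, batch, self.ds.celltype)
        if metric == "pcr":
            return self._pcr(batch)
        raise ValueError(f"unknown metric {metric!r}")

    def _pcr(self, batch: np.ndarray) -> MetricResult:
        from .groupwise import _r2_vs_batch

        if self._pcr_cache is None:
            from .data import select_hvg

            ds = self.ds
            if ds.logexpr is None:
                raise ValueError("pcr requires count/logexpr data")
            genes = select_hvg(ds, min(self.params.n_hvg, ds.n_genes))
            n_pcs = min(self.params.n_pcs_pcr, len(genes), ds.n_cells - 1)
            self._pcr_cache = compute_pca(ds, n_pcs, genes=genes)
        scores, var_exp = self._pcr_cache
        r2 = _r2_vs_batch(scores, batch)
        return MetricResult(
            metric="pcr",
            level="global",
            direction=-1,
            global_score=float((var_exp * r2).sum() / var_exp.sum()),
        )


# ---------------------------------------------------------------------------
# aggregation / standardization / correlation
# ---------------------------------------------------------------------------


def aggregate_scores(result: MetricResult) -> float:
    """Aggregate a metric result to one number.

    Cell level: unweighted mean over cells.  Cell-type level: mean over cell
    types weighted by the number of cells.  Global level: identity.
    """
    if result.level == "cell":
        if result.per_cell is None or result.per_cell.size == 0:
            raise ValueError("empty per-cell scores")
        return float(result.per_cell.mean())
    if result.level == "celltype":
        if not result.per_group:
            raise ValueError("empty per-group scores")
        groups = list(result.per_group)
        w = np.array([result.group_sizes[g] for g in groups], dtype=float)
        v = np.array([result.per_group[g] for g in groups], dtype=float)
        return float((v * w).sum() / w.sum())
    return float(result.global_score)


def standardize_scores(
    scores: Sequence[float], mode: str = "minmax", direction: int = 1
) -> np.ndarray:
    """Standardize a score series and adjust its direction.

    ``minmax``: (x - min) / range; ``zscore``: (x - mean) / sd; the result is
    multiplied by ``-direction`` so the output increases with batch strength
    (mixing-oriented metrics have direction +1 and are flipped).  A constant
    series returns zeros with a warning.
    """
    x = np.asarray(scores, dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("constant score series; standardized to zeros")
        return np.zeros_like(x)
    if mode == "minmax":
        z = (x - x.min()) / np.ptp(x)
    elif mode == "zscore":
        z = (x - x.mean()) / x.std(ddof=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return z * (-direction)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks for ties).

    Returns NaN (with a warning) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# limits
# ---------------------------------------------------------------------------


class Limit(NamedTuple):
    value: float
    reached: bool


def detection_limit(
    scores: Sequence[float], thetas: Sequence[float], frac: float = 0.10
) -> Limit:
    """Smallest theta whose score departs from the batch-free score by more
    than ``frac`` of the series' overall range.

    Requires ``thetas[0] == 0``.  If never exceeded (e.g. a constant
    series), the maximum theta is returned flagged as not reached.
    """
    scores = np.asarray(scores, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if thetas[0] != 0:
        raise ValueError("thetas must start at 0 (batch-free)")
    span = np.ptp(scores)
    dev = np.abs(scores - scores[0])
    hits = np.flatnonzero(dev > frac * span)
    if span == 0 or hits.size == 0:
        return Limit(float(thetas[-1]), False)
    return Limit(float(thetas[hits[0]]), True)


def imbalance_limit(
    scores: Sequence[float],
    fractions: Sequence[float],
    frac: float = 0.05,
    score_range: float | None = None,
) -> Limit:
    """Smallest removed-cell fraction at which the score diverges by more
    than ``frac`` of the score range from the balanced (fraction 0) score.

    ``score_range`` sets the reference range; when ``None``, the observed
    series range is used.  The benchmark harness passes each metric's nominal
    range so that metrics that merely fluctuate around a stable value keep a
    limit of 1 (stable up to complete removal), matching the intended
    reading of the rule.  A constant series gives limit 1 (not reached
    flagging the sentinel at the maximum fraction).
    """
    scores = np.asarray(scores, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if fractions[0] != 0:
        raise ValueError("fractions must start at 0 (balanced)")
    span = np.ptp(scores) if score_range is None else float(score_range)
    dev = np.abs(scores - scores[0])
    hits = np.flatnonzero(dev > frac * span)
    if span == 0 or hits.size == 0:
        return Limit(float(fractions[-1]), False)
    return Limit(float(fractions[hits[0]]), True)


#: nominal score ranges used by the imbalance task, as a function of the
#: number of batches B (and the mm parameters)
def nominal_range(metric: str, n_batches: int, params: MetricParams | None = None) -> float:
    params = params or MetricParams()
    if metric in ("cms", "cms_kmin", "cms_bmin", "entropy", "asw", "pcr", "kbet", "graph"):
        return 1.0
    if metric in ("isi", "wisi", "lisi"):
        return float(max(n_batches - 1, 1))
    if metric == "mm":
        return float(params.k_mm - params.k_pos)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# benchmark series container
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSeries:
    """Per-metric score trajectories over a perturbation series."""

    task: str  # "permutation" | "scaling" | "imbalance" | "characteristics"
    factor_values: np.ndarray
    scores: dict[str, np.ndarray]
    standardized: dict[str, np.ndarray] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    limits: dict[str, Limit] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factor_values = np.asarray(self.factor_values, dtype=float)
        if np.any(np.diff(self.factor_values) <= 0):
            raise ValueError("factor values must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        rows = []
        for metric, sc in self.scores.items():
            for f, s, z in zip(self.factor_values, sc, self.standardized.get(metric, sc)):
                rows.append(
                    {
                        "task": self.task,
                        "metric": metric,
                        "factor": f,
                        "score": s,
                        "standardized_score": z,
                        "rho": self.correlations.get(metric, np.nan),
                        "limit": self.limits[metric].value if metric in self.limits else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _score_all(engine: MetricEngine, metrics: Iterable[str], batch=None, seed: int = 0):
    return {m: aggregate_scores(engine.score(m, batch=batch, seed=seed)) for m in metrics}


def _abs_rho(x, y) -> float:
    """|Spearman rho|, NaN for constant or too-short series."""
    if len(x) < 3:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearman(x, y)
    return abs(rho) if np.isfinite(rho) else np.nan


# ---------------------------------------------------------------------------
# tasks
# ---------------------------------------------------------------------------


def run_permutation_task(
    ds: CellDataset,
    metrics: Sequence[str] = ("cms",),
    fractions: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 2)),
    seed: int = 0,
    params: MetricParams | None = None,
) -> BenchmarkSeries:
    """Negative-control task: permute a growing fraction of batch labels.

    Expression, embedding and cell types stay fixed; each metric is
    re-aggregated per fraction and its |Spearman rho| against the permuted
    fraction reported.
    """
    engine = MetricEngine(ds, params)
    fractions = np.asarray(fractions, dtype=float)
    rng = np.random.default_rng(seed)
    scores = {m: [] for m in metrics}
    for f in fractions:
        batch = ds.batch if f == 0 else permute_batch_labels(ds.batch, f, rng)
        vals = _score_all(engine, metrics, batch=batch, seed=seed)
        for m in metrics:
            scores[m].append(vals[m])
    series = BenchmarkSeries(
        task="permutation",
        factor_values=fractions,
        scores={m: np.asarray(v) for m, v in scores.items()},
    )
    for m in metrics:
        series.correlations[m] = _abs_rho(fractions, series.scores[m])
        series.standardized[m] = standardize_scores(series.scores[m], "zscore", DIRECTIONS[m]) if np.ptp(series.scores[m]) else np.zeros(len(fractions))
    return series


def run_scaling_task(
    sim_params: SimulationParameters,
    metrics: Sequence[str] = ("cms",),
    thetas: Sequence[float] | None = None,
    n_cells: int = 2000,
    seed: int = 0,
    params: MetricParams | None = None,
) -> BenchmarkSeries:
    """Batch-strength scaling task on a simulated series.

    Simulates one dataset per theta (shared cell assignments), scores every
    metric on each, and reports the Spearman correlation with theta and the
    10%-of-range batch detection limit.
    """
    from .simulate import DEFAULT_THETA_GRID

    thetas = list(DEFAULT_THETA_GRID) if thetas is None else list(thetas)
    datasets = simulate_series(sim_params, thetas, n_cells, seed)
    scores = {m: [] for m in metrics}
    for ds in datasets:
        engine = MetricEngine(ds, params)
        vals = _score_all(engine, metrics, seed=seed)
        for m in metrics:
            scores[m].append(vals[m])
    series = BenchmarkSeries(
        task="scaling",
        factor_values=np.asarray(thetas, dtype=float),
        scores={m: np.asarray(v) for m, v in scores.items()},
    )
    for m in metrics:
        series.correlations[m] = _abs_rho(series.factor_values, series.scores[m])
        series.limits[m] = detection_limit(series.scores[m], series.factor_values)
        series.standardized[m] = (
            standardize_scores(series.scores[m], "zscore", DIRECTIONS[m])
            if np.ptp(series.scores[m])
            else np.zeros(len(thetas))
        )
    return series


def run_imbalance_task(
    ds: CellDataset,
    metrics: Sequence[str] = ("pcr",),
    fractions: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 2)),
    celltype: object | None = None,
    batch: object | None = None,
    seed: int = 0,
    params: MetricParams | None = None,
) -> BenchmarkSeries:
    """Batch-imbalance task: remove a growing fraction of one (cell type,
    batch) stratum and track each metric's score.

    Scores are centred by the balanced score and scaled by the metric's
    nominal range; limits use the 5%-of-nominal-range rule.
    """
    if ds.celltype is None:
        raise ValueError("imbalance task requires cell-type labels")
    celltype = np.unique(ds.celltype)[0] if celltype is None else celltype
    batch = np.unique(ds.batch)[0] if batch is None else batch
    fractions = np.asarray(fractions, dtype=float)
    B = len(np.unique(ds.batch))
    params = params or MetricParams()
    scores = {m: [] for m in metrics}
    for f in fractions:
        sub = ds if f == 0 else downsample_batch(ds, celltype, batch, float(f), seed)
        engine = MetricEngine(sub, params)
        vals = _score_all(engine, metrics, seed=seed)
        for m in metrics:
            scores[m].append(vals[m])
    series = BenchmarkSeries(
        task="imbalance",
        factor_values=fractions,
        scores={m: np.asarray(v) for m, v in scores.items()},
    )
    for m in metrics:
        rng_nominal = nominal_range(m, B, params)
        series.limits[m] = imbalance_limit(
            series.scores[m], fractions, score_range=rng_nominal
        )
        series.standardized[m] = (series.scores[m] - series.scores[m][0]) / rng_nominal
    return series


def run_characteristics_task(
    datasets: Sequence[CellDataset],
    metrics: Sequence[str] = ("cms",),
    surrogates: Sequence[float] | None = None,
    seed: int = 0,
    params: MetricParams | None = None,
) -> BenchmarkSeries:
    """Correlation of metric scores with batch-strength surrogates across a
    family of datasets (synthetic stand-in for the real-data task).

    ``surrogates`` defaults to the per-dataset DE proportion from
    :func:`batchmix.simulate.estimate_batch_logfc`.
    """
    from .simulate import estimate_batch_logfc

    if surrogates is None:
        surrogates = [
            estimate_batch_logfc(d if d.logexpr is not None else normalize_log(d)).summaries[
                "de_proportion"
            ]
            for d in datasets
        ]
    surrogates = np.asarray(surrogates, dtype=float)
    scores = {m: [] for m in metrics}
    for d in datasets:
        engine = MetricEngine(d, params)
        vals = _score_all(engine, metrics, seed=seed)
        for m in metrics:
            scores[m].append(vals[m])
    order = np.argsort(surrogates, kind="stable")
    # keep factor values strictly increasing for the container
    ordered = surrogates[order]
    eps = np.arange(len(ordered)) * 1e-12
    series = BenchmarkSeries(
        task="characteristics",
        factor_values=ordered + eps,
        scores={m: np.asarray(v)[order] for m, v in scores.items()},
    )
    for m in metrics:
        series.correlations[m] = _abs_rho(surrogates, scores[m])
    return series


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

_THRESHOLDS = {
    # task: (good test, intermediate test)
    "characteristics": (lambda v: v >= 0.75, lambda v: v >= 0.5),
    "permutation": (lambda v: v >= 0.75, lambda v: v >= 0.5),
    "scaling": (lambda v: v >= 0.9, lambda v: v >= 0.8),
    "detection": (lambda v: v <= 0.6, lambda v: v <= 0.7),
    "imbalance": (lambda v: v >= 0.9, lambda v: v >= 0.75),
}


def categorize(summary: dict[str, dict[str, float]]) -> dict[str, dict[str, str]]:
    """Apply the benchmark thresholds to per-metric task statistics.

    ``summary`` maps task name (characteristics | permutation | scaling |
    detection | imbalance) to {metric: statistic}.  Missing or non-finite
    statistics yield "na".
    """
    out: dict[str, dict[str, str]] = {}
    for task, stats_ in summary.items():
        if task not in _THRESHOLDS:
            raise ValueError(f"unknown task {task!r}")
        good, inter = _THRESHOLDS[task]
        cats = {}
        for metric, v in stats_.items():
            if v is None or not np.isfinite(v):
                cats[metric] = "na"
            elif good(v):
                cats[metric] = "good"
            elif inter(v):
                cats[metric] = "intermediate"
            else:
                cats[metric] = "poor"
        out[task] = cats
    return out


def encode_categories(categories: dict[str, dict[str, str]]) -> dict[str, int]:
    """Total numerical score per metric (good = 2, intermediate = 1, else 0),
    for ranking metrics across tasks."""
    enc = {"good": 2, "intermediate": 1, "poor": 0, "na": 0}
    totals: dict[str, int] = {}
    for task_cats in categories.values():
        for metric, cat in task_cats.items():
            totals[metric] = totals.get(metric, 0) + enc[cat]
    return totals
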