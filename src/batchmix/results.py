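"""Shared result container for batch-mixing metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: direction registry: +1 means larger = more mixed (less batch effect)
DIRECTIONS: dict[str, int] = {
    "cms": 1,
    "cms_kmin": 1,
    "cms_bmin": 1,
    "isi": 1,
    "wisi": 1,
    "lisi": 1,
    "entropy": 1,
    "mm": -1,
    "kbet": -1,
    "graph": 1,
    "asw": 1,
    "pcr": -1,
}


@dataclass
class MetricResult:
    """Per-cell, per-cell-type or global metric scores.

    ``direction`` is +1 when larger values indicate better batch mixing and
    -1 otherwise.  ``global_score`` is the documented aggregation of the
    per-cell / per-group values (unweighted cell mean, or cell-count-weighted
    mean over cell types).
    """

    metric: str
    level: str  # "cell" | "celltype" | "global"
    direction: int
    global_score: float
    per_cell: np.ndarray | None = None
    per_group: dict | None = None
    group_sizes: dict | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.per_cell is not None:
            self.per_cell = np.asarray(self.per_cell, dtype=float)


def make_cell_result(metric: str, per_cell: np.ndarray, params: dict | None = None) -> MetricResult:
    per_cell = np.asarray(per_cell, dtype=float)
    return MetricResult(
        metric=metric,
        level="cell",
        direction=DIRECTIONS[metric],
        global_score=float(per_cell.mean()),
        per_cell=per_cell,
        params=params or {},
    )


def make_group_result(
    metric: str, per_group: dict, group_sizes: dict, params: dict | None = None
) -> MetricResult:
    groups = list(per_group)
    w = np.array([group_sizes[g] for g in groups], dtype=float)
    v = np.array([per_group[g] for g in groups], dtype=float)
    return MetricResult(
        metric=metric,
        level="celltype",
        direction=DIRECTIONS[metric],
        global_score=float((v * w).sum() / w.sum()),
        per_group=dict(per_group),
        group_sizes=dict(group_sizes),
        params=params or {},
    )
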