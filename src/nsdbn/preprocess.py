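"""Expression-matrix preprocessing: imputation, 3-level discretization, event marking.

The downstream multinomial model works on a per-gene 3-level coding
(0 = down-regulated, 1 = normal, 2 = up-regulated) obtained by comparing each
measurement with the gene's average expression level: a fold ratio >= ``up_cut``
(default 1.2) codes as up, <= ``down_cut`` (default 0.70) as down.  Regulation
*events* — the first time point at which a gene crosses a threshold — feed the
potential-regulator scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DetectionError, DiscretizationError, MissingDataError

UP = "up"
DOWN = "down"


@dataclass
class ExpressionMatrix:
    """Real-valued gene x time matrix; NaN marks a missing measurement."""

    values: np.ndarray  # shape (n_genes, T), float
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, t = self.values.shape
        if n < 2 or t < 3:
            raise ValueError(f"need at least 2 genes and 3 time points, got {n}x{t}")
        if len(self.gene_names) != n:
            raise ValueError("gene_names length does not match the matrix")
        if len(set(self.gene_names)) != n:
            raise ValueError("gene names must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_names))


@dataclass
class DiscreteMatrix:
    """Per-gene 3-level coding of an expression matrix.

    ``levels[i, t]`` is 0 (down), 1 (normal) or 2 (up); ``per_gene_mean`` holds
    the reference means the fold ratios were taken against.
    """

    levels: np.ndarray  # shape (n_genes, T), int
    gene_names: list[str]
    per_gene_mean: np.ndarray
    r: int = 3

    @property
    def n_genes(self) -> int:
        return self.levels.shape[0]

    @property
    def n_times(self) -> int:
        return self.levels.shape[1]


@dataclass(frozen=True)
class RegulationEvent:
    """Initial up/down-regulation of one gene under one threshold.

    ``time`` is 1-based; only the first crossing per (gene, direction,
    threshold) is recorded.
    """

    gene: str
    time: int
    direction: str  # UP or DOWN
    threshold: float


def read_expression(path, header: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited matrix: first column gene id, rest time-ordered values.

    Empty cells or "NA" are treated as missing.
    """
    df = pd.read_csv(
        path, sep="\t", header=0 if header else None, index_col=0,
        na_values=["NA", ""], keep_default_na=True,
    )
    return ExpressionMatrix(df.to_numpy(dtype=float), [str(g) for g in df.index])


def write_expression(m: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(m.values, index=m.gene_names)
    df.to_csv(path, sep="\t", header=False, na_rep="NA")


def write_levels(d: DiscreteMatrix, path) -> None:
    pd.DataFrame(d.levels, index=d.gene_names).to_csv(path, sep="\t", header=False)


def impute_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """Fill missing values from neighbours.

    Interior single gaps become the mean of the two flanking values; a missing
    first (last) point copies its right (left) neighbour.  Runs of several
    missing values are filled left-to-right, averaging the already-filled left
    neighbour with the next observed value to the right (or copying the left
    neighbour when nothing observed remains on the right).  Idempotent.
    """
    out = m.copy()
    x = out.values
    for i in range(x.shape[0]):
        row = x[i]
        obs = np.flatnonzero(~np.isnan(row))
        if obs.size == 0:
            raise MissingDataError(f"gene {m.gene_names[i]!r} has no observed values")
        for t in range(row.size):
            if not np.isnan(row[t]):
                continue
            nxt = obs[obs > t]
            right = row[nxt[0]] if nxt.size else None
            if t == 0:
                row[t] = right  # leading gap: copy next observed
            elif right is None:
                row[t] = row[t - 1]  # trailing gap: copy left neighbour
            else:
                row[t] = 0.5 * (row[t - 1] + right)
    return out


def _fold_ratios(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    if np.isnan(m.values).any():
        raise MissingDataError("matrix must be imputed before discretization")
    means = m.values.mean(axis=1)
    bad = means <= 0
    if bad.any():
        names = [m.gene_names[i] for i in np.flatnonzero(bad)]
        raise DiscretizationError(f"nonpositive mean for gene(s) {names}; fold change undefined")
    return m.values / means[:, None], means


def discretize(m: ExpressionMatrix, up_cut: float = 1.2, down_cut: float = 0.70) -> DiscreteMatrix:
    """Code each measurement as down/normal/up by fold change against the gene mean.

    Comparisons are inclusive: ratio >= ``up_cut`` is up, ratio <= ``down_cut``
    is down.
    """
    if not (up_cut > 1 > down_cut > 0):
        raise DiscretizationError("need up_cut > 1 > down_cut > 0")
    ratios, means = _fold_ratios(m)
    levels = np.ones_like(ratios, dtype=np.int64)
    levels[ratios >= up_cut] = 2
    levels[ratios <= down_cut] = 0
    return DiscreteMatrix(levels, list(m.gene_names), means)


def _threshold_grid(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0 or hi <= lo:
        raise DetectionError("threshold range/step must be positive")
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    grid = grid[grid <= hi + 1e-12]
    if grid.size < 2:
        raise DetectionError("grid_step must divide the range into at least 2 thresholds")
    return grid


def detect_events(
    m: ExpressionMatrix,
    up_range: tuple[float, float] = (1.0, 1.2),
    down_range: tuple[float, float] = (0.6, 0.8),
    grid_step: float = 0.05,
) -> list[RegulationEvent]:
    """Mark initial up/down-regulation time points over a grid of thresholds.

    For each threshold on the grid each gene contributes at most one initial up
    event (first t whose fold ratio exceeds the up threshold) and one initial
    down event (first t below the down threshold); the union over the grid is
    deduplicated by (gene, time, direction).  Crossings are strict so that a
    gene sitting exactly at its mean never fires the 1.0 threshold.
    """
    ratios, _ = _fold_ratios(m)
    up_grid = _threshold_grid(*up_range, grid_step)
    down_grid = _threshold_grid(*down_range, grid_step)
    events: dict[tuple[str, int, str], RegulationEvent] = {}
    for i, gene in enumerate(m.gene_names):
        row = ratios[i]
        for u in up_grid:
            hits = np.flatnonzero(row > u)
            if hits.size:
                key = (gene, int(hits[0]) + 1, UP)
                events.setdefault(key, RegulationEvent(gene, int(hits[0]) + 1, UP, float(u)))
        for d in down_grid:
            hits = np.flatnonzero(row < d)
            if hits.size:
                key = (gene, int(hits[0]) + 1, DOWN)
                events.setdefault(key, RegulationEvent(gene, int(hits[0]) + 1, DOWN, float(d)))
    return sorted(events.values(), key=lambda e: (e.gene, e.time, e.direction))
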