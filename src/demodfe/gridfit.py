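"""Grid-search fitting of the demographic model to the 18-statistic vector.

The objective is a scaled squared distance between the simulated and
empirical aggregate statistic vectors, with per-statistic scales taken from
the empirical across-region standard deviations.  A full factorial grid over
25 parameters is infeasible, so the search is an iterative coordinate sweep:
cycle through the free parameters, evaluating each parameter's grid while
holding the others at the current best, until a full cycle brings no
improvement (or the evaluation budget is exhausted); a finer grid is then
laid around the coarse optimum.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

SCALE_FLOOR = 1e-12


def distance(
    sim_stats: pd.Series, emp_stats: pd.Series, scales: pd.Series
) -> float:
    """Sum over statistics of ((sim - emp) / scale)^2, scales floored at eps."""
    missing = [k for k in emp_stats.index if k not in sim_stats.index or pd.isna(sim_stats[k])]
    if missing:
        raise ValueError(f"missing statistics in simulated vector: {missing}")
    s = np.maximum(scales.reindex(emp_stats.index).to_numpy(dtype=float), SCALE_FLOOR)
    resid = (sim_stats.reindex(emp_stats.index).to_numpy(dtype=float)
             - emp_stats.to_numpy(dtype=float)) / s
    return float(np.sum(resid**2))


def residuals(sim_stats: pd.Series, emp_stats: pd.Series, scales: pd.Series) -> pd.Series:
    s = np.maximum(scales.reindex(emp_stats.index).to_numpy(dtype=float), SCALE_FLOOR)
    return (sim_stats.reindex(emp_stats.index) - emp_stats) / s


@dataclass
class ParameterGrid:
    """Per-parameter grid values spanning literature (low, high) ranges."""

    values: dict[str, np.ndarray]

    def __post_init__(self):
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k, v in self.values.items():
            if v.size == 0:
                raise ValueError(f"empty grid for {k}")

    @classmethod
    def from_ranges(cls, ranges: dict[str, tuple[float, float]], points: int = 3) -> "ParameterGrid":
        """Evenly spaced grids containing the range midpoint (odd point counts)."""
        if points % 2 == 0:
            points += 1  # keep the midpoint on the grid
        return cls({k: np.linspace(lo, hi, points) for k, (lo, hi) in ranges.items()})

    def midpoint(self) -> dict[str, float]:
        return {k: float(v[len(v) // 2]) for k, v in self.values.items()}

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def cycle_cost(self) -> int:
        return int(sum(len(v) for v in self.values.values()))


@dataclass
class FitResult:
    best_params: dict[str, float]
    distance: float
    residuals: pd.Series
    trace: list[tuple[dict[str, float], float]] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        rows = [dict(p, distance=d) for p, d in self.trace]
        return pd.DataFrame(rows)


def point_seed(master_seed: int, params: dict[str, float]) -> int:
    """Deterministic per-point seed: same parameter point, same simulations."""
    key = repr(sorted((k, float(v)) for k, v in params.items())).encode()
    return int((zlib.crc32(key) ^ (master_seed * 2654435761)) % (2**31 - 1)) + 1


def _sweep(
    grid: ParameterGrid,
    evaluate: Callable[[dict[str, float]], pd.Series],
    emp_stats: pd.Series,
    scales: pd.Series,
    start: dict[str, float],
    budget: int | None,
    trace: list,
    cache: dict,
) -> tuple[dict[str, float], float]:
    """Iterative per-parameter grid sweeps from ``start``; returns the best
    point and distance.  Evaluations are cached by parameter point."""

    def score(point: dict[str, float]) -> float:
        key = tuple(sorted((k, float(v)) for k, v in point.items()))
        if key not in cache:
            if budget is not None and len(cache) >= budget:
                raise _BudgetExhausted
            cache[key] = distance(evaluate(point), emp_stats, scales)
            trace.append((dict(point), cache[key]))
        return cache[key]

    best = dict(start)
    best_d = score(best)
    try:
        improved = True
        while improved:
            improved = False
            for name in grid.names:
                for value in grid.values[name]:
                    cand = dict(best, **{name: float(value)})
                    d = score(cand)
                    if d < best_d - 1e-15:
                        best, best_d = cand, d
                        improved = True
    except _BudgetExhausted:
        pass
    return best, best_d


class _BudgetExhausted(Exception):
    pass


#: factorial evaluation is used under "auto" when the full grid is this small
FACTORIAL_LIMIT = 250


def coarse_search(
    grid: ParameterGrid,
    emp_stats: pd.Series,
    scales: pd.Series,
    evaluate: Callable[[dict[str, float]], pd.Series],
    budget: int | None = None,
    strategy: str = "auto",
) -> FitResult:
    """Coarse grid search.

    strategy "sweep" runs iterative coordinate sweeps from the grid midpoint
    (the only feasible traversal in high dimension); "factorial" evaluates
    the full grid (immune to ridge-shaped local minima, feasible for few free
    parameters); "auto" picks factorial when the full grid has at most
    FACTORIAL_LIMIT points.
    """
    if budget is not None and budget < grid.cycle_cost():
        raise ValueError(
            f"budget {budget} is below one full sweep cycle ({grid.cycle_cost()} evaluations)"
        )
    n_points = int(np.prod([len(v) for v in grid.values.values()]))
    if strategy == "auto":
        strategy = "factorial" if n_points <= FACTORIAL_LIMIT else "sweep"
    trace: list = []
    cache: dict = {}
    if strategy == "factorial":
        if budget is not None and n_points > budget:
            raise ValueError(f"budget {budget} below factorial grid size {n_points}")
        best, best_d = None, np.inf
        for combo in itertools.product(*(grid.values[k] for k in grid.names)):
            point = {k: float(v) for k, v in zip(grid.names, combo)}
            d = distance(evaluate(point), emp_stats, scales)
            trace.append((dict(point), d))
            if d < best_d:
                best, best_d = point, d
    elif strategy == "sweep":
        best, best_d = _sweep(grid, evaluate, emp_stats, scales, grid.midpoint(),
                              budget, trace, cache)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    res = residuals(evaluate(best), emp_stats, scales)
    return FitResult(best, best_d, res, trace)


def fine_search(
    coarse_result: FitResult,
    grid: ParameterGrid,
    emp_stats: pd.Series,
    scales: pd.Series,
    evaluate: Callable[[dict[str, float]], pd.Series],
    refinement_factor: int = 4,
    budget: int | None = None,
) -> FitResult:
    """Refined search on grids spanning +/- one coarse step around the coarse
    optimum at ``refinement_factor`` x resolution, clipped to declared ranges.

    The coarse best point sits on every fine grid, so the fine distance never
    exceeds the coarse one.
    """
    if refinement_factor < 2:
        raise ValueError("refinement_factor must be >= 2")
    fine_values = {}
    for name, values in grid.values.items():
        best_v = coarse_result.best_params[name]
        if values.size == 1:
            fine_values[name] = values.copy()
            continue
        step = float(np.diff(np.sort(values)).min())
        # fixed fine step = coarse step / refinement_factor; clipping at the
        # declared range drops points instead of squeezing the resolution
        offsets = np.arange(-refinement_factor, refinement_factor + 1)
        pts = best_v + offsets * (step / refinement_factor)
        pts = pts[(pts >= float(values.min()) - 1e-12)
                  & (pts <= float(values.max()) + 1e-12)]
        pts = np.unique(np.append(pts, best_v))
        fine_values[name] = pts
    fine_grid = ParameterGrid(fine_values)
    trace: list = []
    cache: dict = {}
    best, best_d = _sweep(fine_grid, evaluate, emp_stats, scales,
                          dict(coarse_result.best_params), budget, trace, cache)
    if best_d > coarse_result.distance:
        best, best_d = dict(coarse_result.best_params), coarse_result.distance
    res = residuals(evaluate(best), emp_stats, scales)
    return FitResult(best, best_d, res, coarse_result.trace + trace)
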