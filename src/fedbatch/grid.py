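"""Exhaustive TRY landscape evaluation over feed parameter × volume split.

The design space of a two-stage fed-batch is swept on a rectangular grid: one
axis holds the scalar stage-1 feed parameter (constant rate in L/h, linear
ramp in L/h², or exponential set-point growth rate in 1/h), the other the
fraction of the total feed volume delivered during the growth stage. Every
cell is simulated with the same total substrate and final volume, so the
per-substrate yield is the same linear function of the final titer in every
cell and the maximum-titer and maximum-yield strategies coincide. The search
is deliberately exhaustive — each cell has a closed-form solution, so even
fine grids evaluate quickly and no continuous optimizer is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FedBatchError
from .model import (
    ConstantFeed,
    ExponentialFeed,
    FeedStrategy,
    LinearFeed,
    ProcessSetup,
    StagePhysiology,
)
from .simulate import ProcessResult, simulate_process

__all__ = [
    "GridSpec",
    "GridResult",
    "evaluate_grid",
    "select_optimum",
    "tradeoff_frontier",
    "tradeoff_curves",
    "GRID_CSV_COLUMNS",
]

log = logging.getLogger(__name__)

STRATEGY_TYPES = ("constant", "linear", "exponential")

GRID_CSV_COLUMNS = [
    "strategy_param", "frac1", "t1_h", "t2_h", "titer_g_per_L",
    "rate_g_per_L_h", "yield_g_per_g", "x_end_g", "p_end_g", "v_end_L",
    "feasible", "reason",
]


@dataclass(frozen=True)
class GridSpec:
    """Axes of the exhaustive search.

    ``rate_axis`` holds the stage-1 feed parameter values (meaning depends on
    ``strategy_type``); ``frac_axis`` the stage-1 feed-volume fractions in
    [0, 1]. Axes must be strictly increasing with at least two values each.
    """

    strategy_type: str
    rate_axis: tuple
    frac_axis: tuple

    def __post_init__(self) -> None:
        if self.strategy_type not in STRATEGY_TYPES:
            raise ValueError(
                f"strategy_type must be one of {STRATEGY_TYPES}, got {self.strategy_type!r}")
        object.__setattr__(self, "rate_axis", tuple(float(v) for v in self.rate_axis))
        object.__setattr__(self, "frac_axis", tuple(float(v) for v in self.frac_axis))
        for name, axis in (("rate_axis", self.rate_axis), ("frac_axis", self.frac_axis)):
            if len(axis) < 2:
                raise ValueError(f"{name} needs at least 2 values")
            if np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.frac_axis[0] < 0 or self.frac_axis[-1] > 1:
            raise ValueError("frac_axis values must lie in [0, 1]")

    @classmethod
    def from_bounds(cls, strategy_type: str, param_min: float, param_max: float,
                    n_param: int = 50, frac_min: float = 0.05,
                    frac_max: float = 1.0, n_frac: int = 50,
                    log_spacing: bool = False) -> "GridSpec":
        """Linearly (default) or logarithmically spaced axes between bounds.

        The default fraction axis [0.05, 1.0] includes the one-stage endpoint
        so that cases where a single stage beats two stages are visible.
        """
        if log_spacing:
            if param_min <= 0:
                raise ValueError("log spacing requires param_min > 0")
            rate_axis = np.geomspace(param_min, param_max, n_param)
        else:
            rate_axis = np.linspace(param_min, param_max, n_param)
        frac_axis = np.linspace(frac_min, frac_max, n_frac)
        return cls(strategy_type=strategy_type, rate_axis=tuple(rate_axis),
                   frac_axis=tuple(frac_axis))

    def make_strategy(self, param: float, setup: ProcessSetup,
                      phys1: StagePhysiology) -> FeedStrategy:
        """Instantiate the feed strategy for one rate-axis value."""
        if self.strategy_type == "constant":
            return ConstantFeed(rate=param)
        if self.strategy_type == "linear":
            f_start = LinearFeed.default_f_start(setup.x0, phys1, setup.s_f)
            return LinearFeed(f_start=f_start, ramp=param)
        return ExponentialFeed(mu_set=param)


@dataclass
class GridResult:
    """All simulated cells of one grid search plus metadata.

    ``results[i][j]`` corresponds to ``spec.rate_axis[i]``,
    ``spec.frac_axis[j]``. Infeasible cells are retained with NaN metrics and
    a reason code so that exported surfaces stay rectangular.
    """

    spec: GridSpec
    setup: ProcessSetup
    phys1: StagePhysiology
    phys2: StagePhysiology
    results: List[List[ProcessResult]]
    batch_time: float = 0.0

    def iter_cells(self):
        for row in self.results:
            yield from row

    def feasible_cells(self) -> List[ProcessResult]:
        return [r for r in self.iter_cells() if r.feasible]

    @property
    def n_feasible(self) -> int:
        return len(self.feasible_cells())

    def to_frame(self) -> pd.DataFrame:
        """One row per grid cell, rectangular (infeasible cells keep NaNs)."""
        rows = []
        for i, param in enumerate(self.spec.rate_axis):
            for j, frac in enumerate(self.spec.frac_axis):
                r = self.results[i][j]
                rows.append({
                    "strategy_param": param,
                    "frac1": frac,
                    "t1_h": r.t1,
                    "t2_h": r.t2,
                    "titer_g_per_L": r.titer,
                    "rate_g_per_L_h": r.rate,
                    "yield_g_per_g": r.yield_ps,
                    "x_end_g": r.x_end,
                    "p_end_g": r.p_end,
                    "v_end_L": r.v_end,
                    "feasible": r.feasible,
                    "reason": r.reason if r.reason is not None else "",
                })
        return pd.DataFrame(rows, columns=GRID_CSV_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate_grid(setup: ProcessSetup, phys1: StagePhysiology,
                  phys2: StagePhysiology, spec: GridSpec, *,
                  batch_time: float = 0.0,
                  samples_per_stage: int = 50) -> GridResult:
    """Simulate every (feed parameter, feed-volume fraction) combination.

    Each cell runs :func:`~fedbatch.simulate.simulate_process`; feasibility
    enforces the feed-rate bounds over both stages, non-negative growth, and
    ``mu_max`` when set. Raises :class:`FedBatchError` if no cell at all is
    feasible (the grid does not intersect the feasible design space).
    """
    results: List[List[ProcessResult]] = []
    for param in spec.rate_axis:
        row = []
        for frac in spec.frac_axis:
            try:
                strategy = spec.make_strategy(param, setup, phys1)
            except ValueError as exc:
                row.append(ProcessResult(strategy=None, frac1=frac,
                                         feasible=False, reason=str(exc)))
                continue
            result, _ = simulate_process(
                setup, phys1, phys2, strategy, frac,
                samples_per_stage=samples_per_stage, batch_time=batch_time)
            row.append(result)
        results.append(row)
    grid = GridResult(spec=spec, setup=setup, phys1=phys1, phys2=phys2,
                      results=results, batch_time=batch_time)
    if grid.n_feasible == 0:
        raise FedBatchError("empty feasible set: no grid cell satisfies the constraints")
    log.info("grid %dx%d: %d feasible cells", len(spec.rate_axis),
             len(spec.frac_axis), grid.n_feasible)
    return grid


def select_optimum(grid: GridResult, objective: str = "rate") -> ProcessResult:
    """Best feasible cell by ``objective`` ('rate' or 'titer').

    Exact ties are broken towards the lowest stage-1 feed parameter and then
    the lowest feed-volume fraction — gentler feeding tends to be easier to
    run stably, so among equals the least aggressive process wins. Because
    total substrate is fixed, maximizing titer is equivalent to maximizing
    per-substrate yield.
    """
    if objective not in ("rate", "titer"):
        raise ValueError(f"objective must be 'rate' or 'titer', got {objective!r}")
    best = None
    # iterate in (param asc, frac asc) order so the first strict maximum
    # realizes the tie-break
    for row in grid.results:
        for r in row:
            if not r.feasible:
                continue
            value = getattr(r, objective)
            if best is None or value > getattr(best, objective):
                best = r
    if best is None:
        raise FedBatchError("empty feasible set: nothing to select an optimum from")
    return best


def tradeoff_frontier(grid: GridResult) -> List[ProcessResult]:
    """Pareto-nondominated feasible cells in the (titer, rate) plane.

    A cell is dominated if another feasible cell is at least as good in both
    titer and rate and strictly better in one. The frontier is returned in
    order of increasing titer (hence decreasing rate).
    """
    cells = grid.feasible_cells()
    if not cells:
        raise FedBatchError("empty feasible set: no trade-off frontier")
    # sweep by titer desc; keep cells whose rate strictly exceeds the best
    # rate seen so far (which belongs to a cell with >= titer)
    ordered = sorted(cells, key=lambda r: (-r.titer, -r.rate))
    frontier: List[ProcessResult] = []
    best_rate = -np.inf
    for r in ordered:
        if r.rate > best_rate:
            frontier.append(r)
            best_rate = r.rate
    frontier.reverse()
    return frontier


def tradeoff_curves(grid: GridResult) -> pd.DataFrame:
    """(titer, rate) curves over frac1, one curve per rate-axis value.

    Tidy frame with columns strategy_param, frac1, titer_g_per_L,
    rate_g_per_L_h, feasible — the productivity-titer trade-off one line per
    feed parameter.
    """
    df = grid.to_frame()
    return df[["strategy_param", "frac1", "titer_g_per_L",
               "rate_g_per_L_h", "feasible"]].copy()
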