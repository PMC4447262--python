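"""Static and dynamic paleo-habitat stability over a time-sliced stack.

Given an ordered stack of habitat-suitability slices (most recent first,
each with an age in ka), **static stability** aggregates each cell's own
through-time suitability: with per-slice suitabilities floored at
``floor``, the cell value is the exponent of the summed log
suitabilities — the raw product under ``aggregation="product"``, or its
T-th root (the geometric mean, the default) which preserves the same
[0, 1] endpoints and ranking while keeping per-slice interpretability.
A value of 1 means continuously perfect habitat; values near 0 mean the
cell was unsuitable during some or all periods.

**Dynamic stability** recognises that a refugium need not be a static
location: habitat can persist by shifting to track its climate.  A
cell's dynamic stability is the best score attainable by any space-time
path that ends at the cell in the present, where the path occupies one
cell per time slice, scores each slice with the suitability of the cell
it occupies, and may move between consecutive slices only within a
dispersal budget: the least-cost distance (cost ``-ln(suitability)`` on
the destination slice, by default) must not exceed
``speed x Δt x cost_calibration``.  Dispersal can only add options, so
dynamic stability is cellwise >= static stability, equals it exactly at
``speed=0`` (the stationary path is the only one), and is non-decreasing
in speed.

The dispersal budget is expressed in cost-distance units (map units
weighted by ``-ln`` suitability), so movement through perfect habitat is
cheap and unsuitable habitat consumes the budget quickly;
``cost_calibration`` (cost units per map unit of nominal dispersal)
exposes the coupling as an explicit dial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator

from .cost import CostGrid, grid_graph
from .grid import Grid, GridStack

__all__ = [
    "StabilityResult",
    "StabilityModel",
    "static_stability",
    "dynamic_stability",
    "default_age_schedule",
]

_AGGREGATIONS = {"geometric_mean", "product"}


def default_age_schedule() -> list[float]:
    """The standard 62-slice age schedule (ka before present).

    Present back to the last glacial maximum (22 ka) in 1 ka steps, then
    2 ka steps to 80 ka, then 4 ka steps to the last interglacial
    (120 ka).
    """
    ages = list(range(0, 23))          # 0..22 ka, 1 ka steps
    ages += list(range(24, 81, 2))     # 24..80 ka, 2 ka steps
    ages += list(range(84, 121, 4))    # 84..120 ka, 4 ka steps
    return [float(a) for a in ages]


@dataclass
class StabilityResult:
    """A stability surface in [0, 1] plus the settings that produced it."""

    grid: Grid
    mode: str
    aggregation: str
    floor: float
    dispersal_speed: float | None = None
    cost_calibration: float = 1.0
    per_slice_effective: GridStack | None = None


def _prepare(stack: GridStack, floor: float, aggregation: str):
    if len(stack) < 2:
        raise ValueError("stability needs at least two time slices")
    if not (0 < floor < 1):
        raise ValueError(f"floor must lie in (0, 1), got {floor}")
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {sorted(_AGGREGATIONS)}")
    for g in stack:
        g.check_suitability()
    mask = stack.union_mask()
    suit = np.clip(stack.as_array(), floor, 1.0)
    return suit, mask


def _finish(log_total: np.ndarray, n_slices: int, aggregation: str,
            mask: np.ndarray, template: Grid) -> Grid:
    if aggregation == "geometric_mean":
        log_total = log_total / n_slices
    vals = np.exp(log_total)
    vals[mask] = 0.0
    out = template.copy(values=vals)
    out.nodata_mask = mask.copy()
    return out


def static_stability(
    stack: GridStack,
    floor: float = 1e-6,
    aggregation: str = "geometric_mean",
    store_per_slice: bool = False,
) -> StabilityResult:
    """Through-time continuity of suitability, cell by cell."""
    suit, mask = _prepare(stack, floor, aggregation)
    log_total = np.log(suit).sum(axis=0)
    per_slice = None
    if store_per_slice:
        per_slice = GridStack(
            [g.copy(values=s) for g, s in zip(stack.grids, suit)],
            list(stack.ages_ka),
        )
    return StabilityResult(
        grid=_finish(log_total, len(stack), aggregation, mask, stack.grids[0]),
        mode="static", aggregation=aggregation, floor=floor,
        per_slice_effective=per_slice,
    )


def _budget_dilation(graph, values_flat: np.ndarray, budget: float,
                     chunk: int = 512) -> np.ndarray:
    """For each node j: max of values over nodes i with d(i, j) <= budget.

    The graph is undirected, so distances are symmetric and sources can
    be processed in chunks of rows.
    """
    n = values_flat.shape[0]
    out = np.full(n, -np.inf)
    candidates = np.flatnonzero(np.isfinite(values_flat))
    for start in range(0, candidates.size, chunk):
        idx = candidates[start:start + chunk]
        d = dijkstra(graph, directed=False, indices=idx, limit=budget)
        d = np.atleast_2d(d)
        contrib = np.where(d <= budget, values_flat[idx][:, None], -np.inf)
        out = np.maximum(out, contrib.max(axis=0))
    return out


def dynamic_stability(
    stack: GridStack,
    speed: float = 10.0,
    floor: float = 1e-6,
    aggregation: str = "geometric_mean",
    cost_calibration: float = 1.0,
    traversal: str = "destination",
    store_per_slice: bool = False,
) -> StabilityResult:
    """Dispersal-limited shifting-refugia stability.

    Parameters
    ----------
    stack
        Suitability slices, most recent first, with ages in ka.
    speed
        Maximum dispersal speed in map units per year (e.g. 10 for
        10 m/yr on a metre grid).
    floor
        Suitability floor for both scoring and the ``-ln`` cost.
    aggregation
        ``"geometric_mean"`` (default) or ``"product"`` over slices.
    cost_calibration
        Cost-distance units per map unit of dispersal budget.
    traversal
        Which slice's habitat prices movement for a transition:
        ``"destination"`` (younger slice, default), ``"source"`` or
        ``"mean"``.
    store_per_slice
        Keep the cumulative dispersal-constrained stability through each
        slice (geometric mean over slices so far) as a GridStack.
    """
    if speed < 0:
        raise ValueError(f"speed must be non-negative, got {speed}")
    if traversal not in {"destination", "source", "mean"}:
        raise ValueError(f"unknown traversal rule {traversal!r}")
    suit, mask = _prepare(stack, floor, aggregation)
    ages = np.asarray(stack.ages_ka, dtype=float)
    n_slices, nrows, ncols = suit.shape
    logs = np.log(suit)
    logs[:, mask] = -np.inf  # masked cells can neither score nor relay

    # iterate oldest -> present, accumulating the best path log-score
    L = logs[-1].copy()
    partials = [L.copy()]
    for t in range(n_slices - 2, -1, -1):
        dt_years = (ages[t + 1] - ages[t]) * 1000.0
        budget = speed * dt_years * cost_calibration
        if budget > 0:
            if traversal == "destination":
                cost_vals = -logs[t]
            elif traversal == "source":
                cost_vals = -logs[t + 1]
            else:
                cost_vals = 0.5 * (-logs[t] - logs[t + 1])
            ref = stack.grids[t]
            cg = CostGrid(
                values=np.where(mask, 0.0, cost_vals),
                origin_x=ref.origin_x, origin_y=ref.origin_y,
                cell_size=ref.cell_size, impassable_mask=mask, floor=floor,
            )
            graph = grid_graph(cg).tocsr()
            arrived = _budget_dilation(graph, L.ravel(), budget)
            arrived = arrived.reshape(nrows, ncols)
            # the stationary option is always available
            arrived = np.maximum(arrived, L)
        else:
            arrived = L
        L = logs[t] + arrived
        partials.append(L.copy())
    partials.reverse()  # most recent first, matching the stack order

    per_slice = None
    if store_per_slice:
        slices = []
        for t, part in enumerate(partials):
            span = n_slices - t
            vals = np.exp(part / span)
            vals[mask] = 0.0
            g = stack.grids[t].copy(values=vals)
            g.nodata_mask = mask.copy()
            slices.append(g)
        per_slice = GridStack(slices, list(stack.ages_ka))

    return StabilityResult(
        grid=_finish(L, n_slices, aggregation, mask, stack.grids[0]),
        mode="dynamic", aggregation=aggregation, floor=floor,
        dispersal_speed=speed, cost_calibration=cost_calibration,
        per_slice_effective=per_slice,
    )


class StabilityModel(BaseEstimator):
    """Estimator interface over the stability calculations.

    ``fit(stack)`` computes the configured stability surface; fitted
    attributes are ``result_`` (the :class:`StabilityResult`) and
    ``stability_`` (its Grid).
    """

    def __init__(self, mode: str = "dynamic", speed: float = 10.0,
                 floor: float = 1e-6, aggregation: str = "geometric_mean",
                 cost_calibration: float = 1.0,
                 traversal: str = "destination"):
        self.mode = mode
        self.speed = speed
        self.floor = floor
        self.aggregation = aggregation
        self.cost_calibration = cost_calibration
        self.traversal = traversal

    def fit(self, stack: GridStack):
        if self.mode == "static":
            self.result_ = static_stability(
                stack, floor=self.floor, aggregation=self.aggregation)
        elif self.mode == "dynamic":
            self.result_ = dynamic_stability(
                stack, speed=self.speed, floor=self.floor,
                aggregation=self.aggregation,
                cost_calibration=self.cost_calibration,
                traversal=self.traversal)
        else:
            raise ValueError(f"mode must be 'static' or 'dynamic', got {self.mode!r}")
        self.stability_ = self.result_.grid
        return self

    def fit_transform(self, stack: GridStack) -> Grid:
        return self.fit(stack).stability_
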