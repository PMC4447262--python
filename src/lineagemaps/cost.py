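"""Resistance surfaces and least-cost distance on the grid graph.

Habitat suitability ``s`` is converted to a per-cell traversal cost
``-ln(max(s, floor))``, so perfect habitat is free to cross and poor
habitat acts as a barrier.  Least-cost distances are computed on the
8-connected grid graph with the standard cost-distance edge weight: the
arithmetic mean of the two endpoint cell costs, times the geometric step
length (1 for rook moves, sqrt(2) for diagonals), times the cell size.
This matches the conventional GIS CostDistance semantics.

Distances are "map-unit-weighted cost": multiplying every suitability by
a constant shifts all costs, and distances scale with ``cell_size``.
Unreachable cells carry an explicit ``+inf`` sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import Grid, OccurrenceTable, snap_to_cells

__all__ = [
    "CostGrid",
    "DistanceGrid",
    "suitability_to_cost",
    "least_cost_distance",
    "lineage_distances",
]

_SQRT2 = float(np.sqrt(2.0))

# (dr, dc, step length) for the 8-connected neighbourhood; only the four
# "forward" offsets are enumerated, the graph being undirected.
_OFFSETS = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2)]


@dataclass
class CostGrid:
    """Per-cell traversal cost with the geometry of its parent grid."""

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    impassable_mask: np.ndarray
    floor: float = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.impassable_mask = np.asarray(self.impassable_mask, dtype=bool)
        if self.values.shape != self.impassable_mask.shape:
            raise ValueError("cost values and impassable_mask must share shape")
        passable = self.values[~self.impassable_mask]
        if passable.size and (np.any(passable < 0) or not np.all(np.isfinite(passable))):
            raise ValueError("passable costs must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DistanceGrid:
    """Accumulated least-cost distance from the nearest source.

    ``values`` is 0 at every source, ``+inf`` at unreachable cells.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    sources: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_grid(self) -> Grid:
        """Export as a Grid with +inf encoded as nodata."""
        finite = np.isfinite(self.values)
        vals = np.where(finite, self.values, 0.0)
        return Grid(vals, self.origin_x, self.origin_y, self.cell_size,
                    nodata_mask=~finite)


def suitability_to_cost(
    sdm: Grid,
    floor: float = 1e-6,
    impassable_threshold: float | None = None,
) -> CostGrid:
    """Convert a suitability grid to a traversal-cost grid.

    ``cost = -ln(max(s, floor))``; cells with suitability below
    ``impassable_threshold`` (default: ``floor``) and nodata cells are
    flagged impassable and excluded from the graph.
    """
    if not (0 < floor < 1):
        raise ValueError(f"floor must lie in (0, 1), got {floor}")
    sdm.check_suitability()
    if impassable_threshold is None:
        impassable_threshold = floor
    cost = -np.log(np.clip(sdm.values, floor, None))
    impassable = sdm.nodata_mask | (sdm.values < impassable_threshold)
    return CostGrid(cost, sdm.origin_x, sdm.origin_y, sdm.cell_size,
                    impassable, floor=floor)


def grid_graph(cost: CostGrid) -> coo_matrix:
    """Sparse 8-connected graph over the passable cells of a cost grid.

    Node ids are flat row-major cell indices over the full grid; edges
    touching an impassable cell are omitted.  Edge weight between
    adjacent cells a, b is ``mean(cost_a, cost_b) * step * cell_size``.
    """
    nrows, ncols = cost.shape
    n = nrows * ncols
    passable = ~cost.impassable_mask
    rows_i: list[np.ndarray] = []
    cols_j: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    idx = np.arange(n).reshape(nrows, ncols)
    for dr, dc, step in _OFFSETS:
        r0s, r0e = max(0, -dr), min(nrows, nrows - dr)
        c0s, c0e = max(0, -dc), min(ncols, ncols - dc)
        a = idx[r0s:r0e, c0s:c0e]
        b = idx[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        ok = passable[r0s:r0e, c0s:c0e] & passable[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        w = 0.5 * (cost.values[r0s:r0e, c0s:c0e] + cost.values[r0s + dr:r0e + dr, c0s + dc:c0e + dc])
        w = w * step * cost.cell_size
        rows_i.append(a[ok].ravel())
        cols_j.append(b[ok].ravel())
        weights.append(w[ok].ravel())
    i = np.concatenate(rows_i) if rows_i else np.array([], dtype=int)
    j = np.concatenate(cols_j) if cols_j else np.array([], dtype=int)
    w = np.concatenate(weights) if weights else np.array([], dtype=float)
    return coo_matrix((w, (i, j)), shape=(n, n))


def least_cost_distance(
    cost: CostGrid, sources: list[tuple[int, int]]
) -> DistanceGrid:
    """Multi-source least-cost distance over an 8-connected cost grid.

    Every source cell gets distance 0 (even on impassable cells, which
    propagate nothing); unreachable cells get ``+inf``.
    """
    if not sources:
        raise ValueError("at least one source cell is required")
    nrows, ncols = cost.shape
    for r, c in sources:
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise ValueError(f"source {(r, c)} outside grid extent {cost.shape}")
    graph = grid_graph(cost).tocsr()
    flat_sources = [r * ncols + c for r, c in sources
                    if not cost.impassable_mask[r, c]]
    dist = np.full(nrows * ncols, np.inf)
    if flat_sources:
        dist = dijkstra(graph, directed=False, indices=flat_sources,
                        min_only=True)
    dist = dist.reshape(nrows, ncols)
    dist[cost.impassable_mask] = np.inf
    for r, c in sources:
        dist[r, c] = 0.0
    return DistanceGrid(dist, cost.origin_x, cost.origin_y, cost.cell_size,
                        sources=list(sources))


def lineage_distances(
    sdm: Grid,
    records: OccurrenceTable,
    species: str,
    floor: float = 1e-6,
    impassable_threshold: float | None = None,
) -> dict[str, DistanceGrid]:
    """Least-cost distance surface to the nearest record of each lineage.

    Sources for a lineage are the cells containing its sequenced records.
    Lineages whose records all fall outside the raster extent are warned
    about and omitted from the result.
    """
    table = records.for_species(species).sequenced()
    if len(table) == 0:
        raise ValueError(f"species {species!r} has no lineage-labelled records")
    cost = suitability_to_cost(sdm, floor=floor,
                               impassable_threshold=impassable_threshold)
    in_extent, out = snap_to_cells(table, sdm)
    cells_by_lineage: dict[str, list[tuple[int, int]]] = {}
    for i, r, c in in_extent:
        label = table.data.iloc[i]["lineage"]
        cells_by_lineage.setdefault(label, []).append((r, c))
    dropped = set(table.data.iloc[out]["lineage"]) - set(cells_by_lineage)
    if dropped:
        warnings.warn(
            f"lineage(s) {sorted(dropped)} of {species!r} have no in-extent "
            "records and were omitted",
            stacklevel=2,
        )
    if not cells_by_lineage:
        raise ValueError(
            f"species {species!r}: no lineage-labelled record falls inside "
            "the raster extent"
        )
    return {
        label: least_cost_distance(cost, cells)
        for label, cells in sorted(cells_by_lineage.items())
    }
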