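"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they are used to
check: least-cost distances are recomputed with a hand-written binary
heap Dijkstra over an explicitly enumerated edge list, Bray–Curtis with
a naive double loop over the formula, and dynamic stability by direct
iteration of the space-time path recurrence using the brute-force
distances.
"""

from __future__ import annotations

import heapq
import math

import numpy as np
import pytest

from lineagemaps import (
    Barrier,
    GaussianPatch,
    Grid,
    LandscapeSpec,
    make_landscape,
    make_lineage_points,
)

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_dijkstra(
    cost: np.ndarray,
    impassable: np.ndarray,
    sources: list[tuple[int, int]],
    cell_size: float = 1.0,
) -> np.ndarray:
    """Multi-source Dijkstra over an explicit edge list (heapq-based).

    Edge weight between 8-neighbours a, b = mean(cost_a, cost_b) * step
    * cell_size; impassable cells carry no edges but sources on them
    still read 0.
    """
    nrows, ncols = cost.shape
    dist = np.full((nrows, ncols), np.inf)
    heap = []
    for r, c in sources:
        dist[r, c] = 0.0
        if not impassable[r, c]:
            heapq.heappush(heap, (0.0, r, c))
    offsets = [(-1, -1, SQRT2), (-1, 0, 1.0), (-1, 1, SQRT2), (0, -1, 1.0),
               (0, 1, 1.0), (1, -1, SQRT2), (1, 0, 1.0), (1, 1, SQRT2)]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, step in offsets:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols):
                continue
            if impassable[rr, cc] or impassable[r, c]:
                continue
            nd = d + 0.5 * (cost[r, c] + cost[rr, cc]) * step * cell_size
            if nd < dist[rr, cc]:
                dist[rr, cc] = nd
                heapq.heappush(heap, (nd, rr, cc))
    for r, c in sources:
        dist[r, c] = 0.0
    return dist


def naive_bray_curtis(x: np.ndarray) -> np.ndarray:
    """Direct double-loop evaluation of 1 - 2*sum(min)/(sum+sum)."""
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = 2.0 * np.minimum(x[i], x[j]).sum()
            den = x[i].sum() + x[j].sum()
            out[i, j] = 1.0 - num / den
    return out


def path_dp_dynamic_stability(
    suit: np.ndarray,
    ages_ka: list[float],
    speed: float,
    floor: float,
    cell_size: float = 1.0,
    aggregation: str = "geometric_mean",
) -> np.ndarray:
    """Hand-iterated space-time path recurrence for dynamic stability.

    For each transition the set of cells reachable within the budget is
    enumerated explicitly with the brute-force Dijkstra above, and the
    best log-score is propagated cell by cell in Python loops.
    """
    s = np.clip(np.asarray(suit, dtype=float), floor, 1.0)
    T, nrows, ncols = s.shape
    logs = np.log(s)
    impassable = np.zeros((nrows, ncols), dtype=bool)
    L = logs[-1].copy()
    for t in range(T - 2, -1, -1):
        budget = speed * (ages_ka[t + 1] - ages_ka[t]) * 1000.0
        cost = -logs[t]  # destination-slice habitat prices movement
        A = np.full((nrows, ncols), -np.inf)
        if budget > 0:
            for r in range(nrows):
                for c in range(ncols):
                    d = brute_force_dijkstra(cost, impassable, [(r, c)],
                                             cell_size)
                    reach = d <= budget
                    A[r, c] = L[reach].max()
        else:
            A = L.copy()
        L = logs[t] + np.maximum(A, L)
    if aggregation == "geometric_mean":
        L = L / T
    return np.exp(L)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def uniform_grid():
    """10x10 suitability grid of e^-1 (unit traversal cost everywhere)."""
    return Grid(np.full((10, 10), math.exp(-1.0)))


@pytest.fixture
def barrier_landscape():
    """Two Gaussian habitat patches split by a hard zero column."""
    spec = LandscapeSpec(
        shape=(40, 40),
        features=(
            GaussianPatch(center=(10, 8), sd=5.0),
            GaussianPatch(center=(30, 32), sd=5.0),
            Barrier(axis="col", index=20),
        ),
    )
    return make_landscape(spec)


@pytest.fixture
def two_lineage_setup(barrier_landscape):
    """Landscape plus a two-lineage occurrence table, one per patch."""
    points = make_lineage_points(
        barrier_landscape, n_lineages=2, points_per_lineage=5, seed=11
    )
    return barrier_landscape, points


def random_suitability(rng: np.random.Generator, shape=(20, 20),
                       zero_frac: float = 0.0) -> Grid:
    vals = rng.random(shape)
    if zero_frac > 0:
        vals[rng.random(shape) < zero_frac] = 0.0
    return Grid(vals)
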