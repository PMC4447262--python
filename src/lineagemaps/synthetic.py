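"""Seeded synthetic inputs for the whole pipeline.

Real inputs to the method are continental suitability rasters, sequenced
lineage localities, and stacks of paleo-suitability hindcasts.  This
module generates structurally equivalent toy versions — suitability
landscapes built from Gaussian habitat patches, ridges and hard
barriers (emulating an archipelago of mesic habitat islands in a drier
matrix); lineage occurrence points clustered in distinct patches, with
unlabelled species-only records alongside; and time series in which the
habitat features drift across the grid to exercise the shifting-refugia
model.  Everything is a pure function of its spec and seed: identical
inputs give bit-identical outputs.

It also ships a small packaged fixture: the published per-genus
inventory of rainforest-specialist lizard and frog lineages of eastern
Australia (13 genus rows with species, lineage and sequenced-record
counts, plus the totals row as printed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .grid import Grid, GridStack, OccurrenceTable

__all__ = [
    "GaussianPatch",
    "Ridge",
    "Barrier",
    "LandscapeSpec",
    "LineageInventoryRow",
    "make_landscape",
    "make_lineage_points",
    "make_time_series",
    "table1_fixture",
    "inventory_printed_totals",
]


@dataclass(frozen=True)
class GaussianPatch:
    """An isotropic Gaussian habitat patch (peak value at its centre)."""

    center: tuple[float, float]  # (row, col)
    sd: float
    peak: float = 1.0


@dataclass(frozen=True)
class Ridge:
    """A linear habitat band across the whole grid.

    ``axis="row"`` runs along a row (constant row position),
    ``axis="col"`` along a column.
    """

    axis: str
    position: float
    width: float
    peak: float = 1.0


@dataclass(frozen=True)
class Barrier:
    """A hard dispersal barrier: cells set to zero suitability.

    ``axis="col"`` zeroes a full (or partial) column, ``axis="row"`` a
    row; ``span`` optionally limits the cross-range as ``(start, stop)``.
    """

    axis: str
    index: int
    span: tuple[int, int] | None = None


@dataclass(frozen=True)
class LandscapeSpec:
    """Deterministic recipe for a synthetic suitability landscape."""

    shape: tuple[int, int] = (60, 60)
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float | None = None  # defaults to n_rows * cell_size
    features: tuple = ()
    seed: int = 0

    @property
    def top_origin_y(self) -> float:
        return (self.shape[0] * self.cell_size
                if self.origin_y is None else self.origin_y)


def _check_inside(name: str, row: float, col: float, shape: tuple[int, int]):
    if not (0 <= row < shape[0] and 0 <= col < shape[1]):
        raise ValueError(
            f"{name} centre ({row}, {col}) lies outside grid {shape}"
        )


def make_landscape(spec: LandscapeSpec) -> Grid:
    """Render a landscape spec into a suitability Grid in [0, 1].

    Gaussian patches and ridges are summed and clipped to [0, 1];
    barriers are applied last and force cells to exactly 0.
    """
    nrows, ncols = spec.shape
    vals = np.zeros((nrows, ncols))
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    for feat in spec.features:
        if isinstance(feat, GaussianPatch):
            r0, c0 = feat.center
            _check_inside("gaussian_patch", r0, c0, spec.shape)
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            vals += feat.peak * np.exp(-d2 / (2.0 * feat.sd**2))
        elif isinstance(feat, Ridge):
            if feat.axis not in {"row", "col"}:
                raise ValueError(f"ridge axis must be 'row' or 'col', got {feat.axis!r}")
            coord = rr if feat.axis == "row" else cc
            limit = nrows if feat.axis == "row" else ncols
            if not (0 <= feat.position < limit):
                raise ValueError(f"ridge position {feat.position} outside grid")
            vals += feat.peak * np.exp(
                -((coord - feat.position) ** 2) / (2.0 * feat.width**2)
            )
        elif isinstance(feat, Barrier):
            continue  # applied after clipping
        else:
            raise TypeError(f"unknown landscape feature {feat!r}")
    vals = np.clip(vals, 0.0, 1.0)
    for feat in spec.features:
        if isinstance(feat, Barrier):
            if feat.axis not in {"row", "col"}:
                raise ValueError(f"barrier axis must be 'row' or 'col', got {feat.axis!r}")
            limit = ncols if feat.axis == "col" else nrows
            if not (0 <= feat.index < limit):
                raise ValueError(f"barrier index {feat.index} outside grid")
            lo, hi = feat.span if feat.span is not None else (0, None)
            if feat.axis == "col":
                vals[lo:hi, feat.index] = 0.0
            else:
                vals[feat.index, lo:hi] = 0.0
    return Grid(vals, origin_x=spec.origin_x, origin_y=spec.top_origin_y,
                cell_size=spec.cell_size)


def make_lineage_points(
    landscape: Grid,
    n_lineages: int,
    points_per_lineage: int,
    min_suitability: float = 0.2,
    seed: int = 0,
    species: str = "sp1",
    n_species_records: int | None = None,
) -> OccurrenceTable:
    """Sample lineage-labelled and species-only records on a landscape.

    Lineage centres are spread across distinct high-suitability areas
    (first centre at the suitability maximum, then farthest-point
    placement among eligible cells); each lineage's records are drawn
    from the eligible cells nearest its centre.  Unlabelled species
    records (mimicking museum/atlas data without lineage identity) are
    drawn from all eligible cells.
    """
    if n_lineages < 1 or points_per_lineage < 1:
        raise ValueError("n_lineages and points_per_lineage must be >= 1")
    vals = np.where(landscape.nodata_mask, -np.inf, landscape.values)
    eligible = np.argwhere(vals >= min_suitability)
    if len(eligible) < n_lineages:
        raise ValueError(
            f"only {len(eligible)} cell(s) with suitability >= "
            f"{min_suitability}: not enough habitat for {n_lineages} lineages"
        )
    rng = np.random.default_rng(seed)

    flat = vals[eligible[:, 0], eligible[:, 1]]
    centers = [eligible[int(np.argmax(flat))]]
    while len(centers) < n_lineages:
        d2 = np.min(
            [((eligible - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        centers.append(eligible[int(np.argmax(d2))])

    rows = []
    for k, center in enumerate(centers):
        label = f"lin{k + 1}"
        d2 = ((eligible - center) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")
        pool = eligible[order[: max(3 * points_per_lineage, points_per_lineage)]]
        take = rng.choice(
            len(pool), size=points_per_lineage,
            replace=len(pool) < points_per_lineage,
        )
        for r, c in pool[take]:
            x, y = landscape.cell_center(int(r), int(c))
            rows.append((species, label, x, y))

    if n_species_records is None:
        n_species_records = n_lineages * points_per_lineage
    take = rng.choice(len(eligible), size=n_species_records,
                     replace=len(eligible) < n_species_records)
    for r, c in eligible[take]:
        x, y = landscape.cell_center(int(r), int(c))
        rows.append((species, "", x, y))
    return OccurrenceTable.from_records(rows)


def make_time_series(
    spec: LandscapeSpec,
    n_slices: int,
    drift_cells_per_slice: float,
    ages: list[float],
) -> GridStack:
    """A suitability time series with features drifting across the grid.

    Slice 0 is the present and renders *spec* unchanged; each older
    slice shifts every patch/ridge position by ``drift_cells_per_slice``
    columns (toward lower column indices per slice into the past).  An
    error is raised if drift pushes a feature centre off the grid.
    """
    if n_slices != len(ages):
        raise ValueError("n_slices must equal len(ages)")
    grids = []
    for i in range(n_slices):
        shift = drift_cells_per_slice * i
        feats = []
        for feat in spec.features:
            if isinstance(feat, GaussianPatch):
                feats.append(replace(
                    feat, center=(feat.center[0], feat.center[1] - shift)))
            elif isinstance(feat, Ridge) and feat.axis == "col":
                feats.append(replace(feat, position=feat.position - shift))
            else:
                feats.append(feat)
        grids.append(make_landscape(replace(spec, features=tuple(feats))))
    return GridStack(grids, [float(a) for a in ages])


# ---------------------------------------------------------------------------
# Packaged lineage inventory fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineageInventoryRow:
    """One genus of the packaged lineage inventory."""

    family: str
    genus: str
    species_count: int
    lineage_count: int
    record_count: int
    sources: str


# Totals as printed in the published inventory's Total row.  Note: the
# printed record total does not equal the sum of the printed per-genus
# record counts (which is 7983); both are exposed so callers can decide
# which to trust.
_PRINTED_TOTALS = {"species": 53, "lineages": 102, "records": 8703}


def inventory_printed_totals() -> dict[str, int]:
    """The Total row of the published inventory, as printed."""
    return dict(_PRINTED_TOTALS)


def table1_fixture() -> list[LineageInventoryRow]:
    """The packaged per-genus lineage inventory (13 rows)."""
    path = resources.files("lineagemaps") / "data" / "table1_lineage_inventory.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, dtype={"sources": str})
    return [
        LineageInventoryRow(
            family=row.family, genus=row.genus,
            species_count=int(row.species_count),
            lineage_count=int(row.lineage_count),
            record_count=int(row.record_count),
            sources=str(row.sources),
        )
        for row in df.itertuples(index=False)
    ]
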