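"""Lineage distribution models (LDMs).

The core method: partition each cell's species-level habitat suitability
among the intraspecific lineages, weighting each lineage by the inverse
square of its least-cost distance (through suitable habitat) to the
nearest sequenced record of that lineage.  At every cell where at least
one lineage is reachable, the per-lineage values sum exactly to the
species suitability — the species model is divided, never inflated.

Rationale: an unsequenced location most likely belongs to the lineage
that is best connected to it through suitable habitat, so nearby,
well-connected lineages take most of the local suitability and poorly
connected lineages take little.  Cost distance (per-cell cost
``-ln(suitability)``) rather than straight-line distance lets unsuitable
habitat act as a barrier between lineages.

Weighting details:

* ``w_l(c) = max(d_l(c), d0) ** -exponent`` with ``exponent = 2`` by
  default (inverse-square).
* Lineages at *exactly* zero cost distance from a cell (the cell holds
  one of their own records, or is connected to one through perfectly
  suitable habitat) take the cell exclusively, split equally among such
  ties.  This keeps a lineage's own source cells fully assigned to it.
* ``d0`` (default ``0.5 * cell_size``) bounds the weight of strictly
  positive but tiny distances.
* Unreachable lineages (infinite distance) get weight 0; cells where no
  lineage is reachable keep the suitability unallocated (all-zero) and
  are reported rather than silently assigned.

Very small LDM values spread over wide areas; values below ``min_value``
(default 0.01) are zeroed by :func:`apply_min_value` to keep downstream
calculations compact, and downstream normalisations use the post-filter
totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cost import lineage_distances
from .grid import Grid, OccurrenceTable

__all__ = [
    "LineageModelSet",
    "LineageDistributionModel",
    "fit_ldm",
    "apply_min_value",
    "transect_profile",
]


@dataclass
class LineageModelSet:
    """Per-lineage suitability grids for one species.

    At every unmasked cell where at least one lineage is reachable the
    per-lineage values sum to the species suitability (before
    ``min_value`` filtering).
    """

    species: str
    lineages: list[str]
    models: dict[str, Grid]
    sdm: Grid
    min_value: float = 0.01
    min_value_applied: bool = False
    unallocated_mask: np.ndarray | None = None
    source_cells: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.models) != sorted(self.lineages):
            raise ValueError("models must have exactly one grid per lineage")
        for label, g in self.models.items():
            if not g.same_geometry(self.sdm):
                raise ValueError(f"model {label!r} does not share sdm geometry")
        if self.unallocated_mask is None:
            self.unallocated_mask = np.zeros(self.sdm.shape, dtype=bool)

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def model_arrays(self) -> np.ndarray:
        """(n_lineages, rows, cols) stack in ``lineages`` order."""
        return np.stack([self.models[l].values for l in self.lineages])

    def total(self) -> np.ndarray:
        return self.model_arrays().sum(axis=0)


def fit_ldm(
    sdm: Grid,
    records: OccurrenceTable,
    species: str,
    exponent: float = 2.0,
    floor: float = 1e-6,
    min_value: float = 0.01,
    d0: float | None = None,
    impassable_threshold: float | None = None,
) -> LineageModelSet:
    """Fit lineage distribution models for one species.

    Returns the unfiltered partition (conservation holds exactly); pass
    the result through :func:`apply_min_value` to zero trace values.

    Parameters
    ----------
    sdm
        Species habitat-suitability grid, values in [0, 1].
    records
        Occurrence table; only lineage-labelled records of *species* are
        used as cost-distance sources.
    exponent
        Distance-decay exponent of the weights (2 = inverse-square).
    floor
        Suitability floor for the ``-ln`` cost transform.
    min_value
        Exclusion threshold stored on the result (not yet applied).
    d0
        Distance regularisation; defaults to ``0.5 * cell_size``.
    impassable_threshold
        Suitability below which cells are excluded from the cost graph
        (default: ``floor``).
    """
    sdm.check_suitability()
    if d0 is None:
        d0 = 0.5 * sdm.cell_size
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    distances = lineage_distances(
        sdm, records, species, floor=floor,
        impassable_threshold=impassable_threshold,
    )
    lineages = sorted(distances)
    params = {
        "exponent": float(exponent),
        "floor": float(floor),
        "d0": float(d0),
        "impassable_threshold": float(
            floor if impassable_threshold is None else impassable_threshold
        ),
    }
    base = np.where(sdm.nodata_mask, 0.0, sdm.values)

    if len(lineages) == 1:
        # degenerate partition: the lineage model is the species model
        only = lineages[0]
        models = {only: sdm.copy(values=base)}
        return LineageModelSet(
            species=species, lineages=lineages, models=models, sdm=sdm,
            min_value=min_value,
            source_cells={only: distances[only].sources},
            params=params,
        )

    dist = np.stack([distances[l].values for l in lineages])
    n_l = len(lineages)
    weights = np.zeros_like(dist)
    zero = dist == 0.0
    any_zero = zero.any(axis=0)
    finite = np.isfinite(dist)
    # strictly positive finite distances: inverse-power weight, floored at d0
    pos = finite & ~zero
    weights[pos] = np.maximum(dist[pos], d0) ** (-float(exponent))
    # zero-distance ties take the cell exclusively, split equally
    weights[:, any_zero] = 0.0
    weights[zero] = 1.0

    wsum = weights.sum(axis=0)
    reachable = wsum > 0
    share = np.zeros_like(weights)
    share[:, reachable] = weights[:, reachable] / wsum[reachable]
    model_values = share * base[None, :, :]

    unallocated = (~reachable) & (~sdm.nodata_mask) & (base > 0)
    if unallocated.any():
        warnings.warn(
            f"{species}: {int(unallocated.sum())} suitable cell(s) are "
            "unreachable from every lineage; their suitability is left "
            "unallocated",
            stacklevel=2,
        )
    models = {
        label: sdm.copy(values=model_values[i])
        for i, label in enumerate(lineages)
    }
    return LineageModelSet(
        species=species, lineages=lineages, models=models, sdm=sdm,
        min_value=min_value, unallocated_mask=unallocated,
        source_cells={l: distances[l].sources for l in lineages},
        params=params,
    )


def apply_min_value(
    model_set: LineageModelSet, min_value: float | None = None
) -> LineageModelSet:
    """Zero model values below the exclusion threshold.

    Values ``< min_value`` are set to 0 (the boundary value is kept).
    The returned set is flagged so downstream normalisations know they
    are working with post-filter totals.
    """
    if min_value is None:
        min_value = model_set.min_value
    if min_value < 0:
        raise ValueError("min_value must be non-negative")
    models: dict[str, Grid] = {}
    for label, g in model_set.models.items():
        vals = np.where(g.values < min_value, 0.0, g.values)
        if min_value > 0 and not np.any(vals > 0):
            warnings.warn(
                f"{model_set.species}/{label}: all model values fall below "
                f"min_value={min_value}; lineage model is all-zero",
                stacklevel=2,
            )
        models[label] = g.copy(values=vals)
    return LineageModelSet(
        species=model_set.species,
        lineages=list(model_set.lineages),
        models=models,
        sdm=model_set.sdm,
        min_value=min_value,
        min_value_applied=min_value > 0,
        unallocated_mask=model_set.unallocated_mask.copy(),
        source_cells=dict(model_set.source_cells),
        params=dict(model_set.params),
    )


def transect_profile(
    model_set: LineageModelSet, line: list[tuple[int, int]]
) -> pd.DataFrame:
    """Stacked per-lineage values along a transect of cells.

    One row per cell, one column per lineage, plus a ``total`` column.
    On an unfiltered set the total equals the species suitability along
    the line.
    """
    nrows, ncols = model_set.sdm.shape
    for r, c in line:
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise ValueError(f"transect cell {(r, c)} outside grid extent")
    rows = []
    for r, c in line:
        rec: dict = {"row": r, "col": c}
        for label in model_set.lineages:
            rec[label] = model_set.models[label].values[r, c]
        rec["total"] = sum(rec[l] for l in model_set.lineages)
        rows.append(rec)
    return pd.DataFrame(rows)


class LineageDistributionModel(BaseEstimator):
    """Estimator interface to the lineage-partitioning method.

    ``fit(sdm, occurrences)`` partitions the species suitability grid
    among the lineages labelled in the occurrence table and applies the
    ``min_value`` exclusion.  Fitted attributes:

    ``model_set_``
        The filtered :class:`LineageModelSet`.
    ``model_set_raw_``
        The unfiltered partition (exact conservation).
    ``models_`` / ``lineages_`` / ``n_lineages_``
        Convenience views of the filtered set.

    Parameters follow the method defaults: inverse-square weighting
    (``exponent=2``), suitability floor ``1e-6`` for the cost transform,
    and exclusion of model values below ``min_value=0.01``.
    """

    def __init__(
        self,
        species: str | None = None,
        exponent: float = 2.0,
        floor: float = 1e-6,
        min_value: float = 0.01,
        d0: float | None = None,
        impassable_threshold: float | None = None,
    ):
        self.species = species
        self.exponent = exponent
        self.floor = floor
        self.min_value = min_value
        self.d0 = d0
        self.impassable_threshold = impassable_threshold

    def fit(self, sdm: Grid, occurrences: OccurrenceTable):
        if not isinstance(sdm, Grid):
            raise TypeError("sdm must be a Grid")
        species = self.species
        if species is None:
            candidates = occurrences.sequenced().species
            if len(candidates) != 1:
                raise ValueError(
                    "species= must be given when the occurrence table holds "
                    f"records for {len(candidates)} species"
                )
            species = candidates[0]
        raw = fit_ldm(
            sdm, occurrences, species,
            exponent=self.exponent, floor=self.floor,
            min_value=self.min_value, d0=self.d0,
            impassable_threshold=self.impassable_threshold,
        )
        self.species_ = species
        self.model_set_raw_ = raw
        self.model_set_ = apply_min_value(raw)
        self.models_ = self.model_set_.models
        self.lineages_ = list(self.model_set_.lineages)
        self.n_lineages_ = len(self.lineages_)
        self.unallocated_mask_ = self.model_set_.unallocated_mask
        return self

    def transect(self, line: list[tuple[int, int]], filtered: bool = False):
        """Per-lineage profile along a transect of (row, col) cells."""
        self._check_fitted()
        ms = self.model_set_ if filtered else self.model_set_raw_
        return transect_profile(ms, line)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_set_"):
            raise AttributeError("this LineageDistributionModel is not fitted yet")
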