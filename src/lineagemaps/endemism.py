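"""Richness and endemism surfaces from suitability and lineage models.

Model-weighted endemism (MWE) is the headline metric: for lineage *l*
with model values :math:`m_l(c)` the cell score is

.. math:: \\mathrm{MWE}(c) = \\sum_l \\frac{m_l(c)}{\\sum_{c'} m_l(c')}

so each lineage contributes a total mass of exactly 1 distributed over
its modelled range, and a cell scores highly where it holds a large
share of the range of one or more lineages.  Richness sums raw
suitabilities (a probabilistic richness, not a count); classical
weighted endemism (WE) thresholds to presence/absence and sums
1/range-size.  The lineage-minus-species difference surface highlights
cells where intraspecific structure is concentrated: places that look
unremarkable at species level but hold range-restricted lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import Grid

__all__ = [
    "EndemismSurface",
    "model_weighted_endemism",
    "model_weighted_richness",
    "weighted_endemism",
    "endemism_difference",
]


@dataclass
class EndemismSurface:
    """A per-cell score grid plus provenance of its contributing models."""

    grid: Grid
    metric: str
    inputs_digest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in {"mwe", "richness", "we", "difference"}:
            raise ValueError(f"unknown endemism metric {self.metric!r}")


def _check_shared_geometry(grids: list[Grid]) -> Grid:
    if not grids:
        raise ValueError("at least one grid is required")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError("all grids must share geometry")
    return ref


def model_weighted_endemism(models: list[Grid] | dict[str, Grid]) -> EndemismSurface:
    """Model-weighted endemism over a collection of (lineage) models.

    Each model is normalised by its own map total, so the whole-map sum
    of the result equals the number of contributing models.  Models with
    zero total are dropped with a warning.
    """
    if isinstance(models, dict):
        labels = sorted(models)
        grids = [models[k] for k in labels]
    else:
        grids = list(models)
        labels = [str(i) for i in range(len(grids))]
    ref = _check_shared_geometry(grids)
    score = np.zeros(ref.shape)
    kept = 0
    for label, g in zip(labels, grids):
        vals = np.where(g.nodata_mask, 0.0, g.values)
        total = vals.sum()
        if total <= 0:
            warnings.warn(
                f"model {label!r} has zero total and was dropped from MWE",
                stacklevel=2,
            )
            continue
        score += vals / total
        kept += 1
    if kept == 0:
        raise ValueError("no model with positive total value")
    return EndemismSurface(
        grid=ref.copy(values=score),
        metric="mwe",
        inputs_digest={"n_models": kept, "labels": labels},
    )


def model_weighted_richness(sdms: list[Grid] | dict[str, Grid]) -> EndemismSurface:
    """Summed habitat suitability: a probabilistic richness surface.

    Because lineage models of a species sum to the species model,
    richness computed from lineage models equals species richness.
    """
    if isinstance(sdms, dict):
        sdms = [sdms[k] for k in sorted(sdms)]
    grids = list(sdms)
    ref = _check_shared_geometry(grids)
    score = np.zeros(ref.shape)
    for g in grids:
        score += np.where(g.nodata_mask, 0.0, g.values)
    return EndemismSurface(
        grid=ref.copy(values=score),
        metric="richness",
        inputs_digest={"n_models": len(grids)},
    )


def weighted_endemism(
    ranges: list[Grid] | dict[str, Grid], presence_threshold: float = 0.01
) -> EndemismSurface:
    """Classical range-weighted endemism on thresholded ranges.

    Presence is ``value >= presence_threshold``; each taxon contributes
    ``1 / range_size`` to every presence cell, so its map-total
    contribution is exactly 1.  Taxa with no presence cell are dropped
    with a warning.
    """
    if isinstance(ranges, dict):
        labels = sorted(ranges)
        grids = [ranges[k] for k in labels]
    else:
        grids = list(ranges)
        labels = [str(i) for i in range(len(grids))]
    ref = _check_shared_geometry(grids)
    score = np.zeros(ref.shape)
    kept = 0
    for label, g in zip(labels, grids):
        presence = (~g.nodata_mask) & (g.values >= presence_threshold)
        size = int(presence.sum())
        if size == 0:
            warnings.warn(
                f"taxon {label!r} has no presence cell at threshold "
                f"{presence_threshold} and was dropped",
                stacklevel=2,
            )
            continue
        score[presence] += 1.0 / size
        kept += 1
    if kept == 0:
        raise ValueError("no taxon with a non-empty thresholded range")
    return EndemismSurface(
        grid=ref.copy(values=score),
        metric="we",
        inputs_digest={"n_taxa": kept, "presence_threshold": presence_threshold},
    )


def endemism_difference(
    lineage_endemism: EndemismSurface, species_endemism: EndemismSurface
) -> EndemismSurface:
    """Cellwise lineage-minus-species endemism.

    Positive cells hold more lineage- than species-level endemism —
    concentrations of spatially restricted intraspecific diversity that
    a species-level analysis would miss.  Both inputs must carry the
    same metric (normally MWE at lineage and at species level).
    """
    if lineage_endemism.metric != species_endemism.metric:
        raise ValueError(
            "metric mismatch: "
            f"{lineage_endemism.metric!r} vs {species_endemism.metric!r}"
        )
    a, b = lineage_endemism.grid, species_endemism.grid
    if not a.same_geometry(b):
        raise ValueError("endemism surfaces must share geometry")
    diff = a.values - b.values
    out = a.copy(values=diff)
    out.nodata_mask = a.nodata_mask | b.nodata_mask
    return EndemismSurface(
        grid=out,
        metric="difference",
        inputs_digest={
            "lineage": lineage_endemism.inputs_digest,
            "species": species_endemism.inputs_digest,
        },
    )
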