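"""Bioregionalization by compositional turnover of lineage models.

Lineage models are aggregated to coarse cells (summing model values in
each block — e.g. factor 20 takes a 0.01-degree grid to 0.2 degrees),
every coarse cell becomes a site with the per-lineage summed model value
as its "abundance", and sites are compared with the Bray–Curtis
dissimilarity

.. math:: D(i, j) = 1 - \\frac{2 \\sum_l \\min(x_{il}, x_{jl})}
                          {\\sum_l x_{il} + \\sum_l x_{jl}}

(0 = identical composition, 1 = no shared lineages).  Agglomerative
clustering of the dissimilarity matrix yields a dendrogram whose deep
splits mark biogeographic breaks, and cutting it (at a height or into k
groups) labels each site with a region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .grid import Grid, aggregate_sum

__all__ = [
    "CompositionMatrix",
    "RegionClassification",
    "BioregionClassifier",
    "build_composition",
    "bray_curtis",
    "cluster_regions",
]

_LINKAGE_METHODS = {"upgma": "average", "average": "average",
                    "complete": "complete", "ward": "ward"}


@dataclass
class CompositionMatrix:
    """Sites x taxa abundance-like matrix of summed lineage-model values.

    Sites are coarse-cell ``(row, col)`` identifiers in row-major order;
    all-zero sites are dropped at construction.
    """

    sites: list[tuple[int, int]]
    taxa: list[str]
    values: np.ndarray
    cell_size: float = 1.0
    factor: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.taxa)):
            raise ValueError("values must be (n_sites, n_taxa)")
        if np.any(self.values < 0):
            raise ValueError("composition values must be non-negative")
        if len(self.sites) and np.any(self.values.sum(axis=1) == 0):
            raise ValueError("all-zero site rows must be dropped before use")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class RegionClassification:
    """Region labels per site plus the dendrogram they were cut from."""

    sites: list[tuple[int, int]]
    labels: np.ndarray
    linkage_matrix: np.ndarray
    linkage_method: str
    cut: dict = field(default_factory=dict)

    @property
    def site_labels(self) -> dict[tuple[int, int], int]:
        return {s: int(l) for s, l in zip(self.sites, self.labels)}

    @property
    def n_regions(self) -> int:
        return len(np.unique(self.labels))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string.

        Leaf names are ``r<row>_c<col>``; branch lengths are differences
        of merge heights (leaves sit at height 0).
        """
        root = to_tree(self.linkage_matrix)
        names = [f"r{r}_c{c}" for r, c in self.sites]

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"

    def to_raster(self, template_shape: tuple[int, int],
                  origin_x: float = 0.0, origin_y: float = 0.0,
                  cell_size: float = 1.0) -> Grid:
        """Categorical raster of region ids at the coarse resolution."""
        vals = np.zeros(template_shape)
        mask = np.ones(template_shape, dtype=bool)
        for (r, c), label in zip(self.sites, self.labels):
            vals[r, c] = label
            mask[r, c] = False
        return Grid(vals, origin_x, origin_y, cell_size, mask)


def build_composition(
    models: dict[str, Grid] | list[Grid], factor: int = 20
) -> CompositionMatrix:
    """Aggregate lineage models into a sites x taxa composition matrix.

    Each model grid is block-summed by *factor*; coarse cells with any
    nonzero value across taxa become sites (row-major order).
    """
    if isinstance(models, dict):
        taxa = sorted(models)
        grids = [models[k] for k in taxa]
    else:
        grids = list(models)
        taxa = [str(i) for i in range(len(grids))]
    if not grids:
        raise ValueError("at least one model grid is required")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError("all model grids must share geometry")
    coarse = [aggregate_sum(g, factor) for g in grids]
    stack = np.stack([c.values for c in coarse])  # (taxa, rows, cols)
    nonzero = stack.sum(axis=0) > 0
    if not nonzero.any():
        warnings.warn("all-zero landscape: empty composition matrix",
                      stacklevel=2)
    rows, cols = np.nonzero(nonzero)  # row-major order
    sites = [(int(r), int(c)) for r, c in zip(rows, cols)]
    values = stack[:, rows, cols].T
    return CompositionMatrix(
        sites=sites, taxa=taxa, values=values,
        cell_size=coarse[0].cell_size, factor=int(factor),
    )


def bray_curtis(matrix: CompositionMatrix | np.ndarray) -> np.ndarray:
    """Square Bray–Curtis dissimilarity matrix between sites."""
    values = matrix.values if isinstance(matrix, CompositionMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two sites")
    if np.any(values < 0):
        raise ValueError("abundances must be non-negative")
    if np.any(values.sum(axis=1) == 0):
        raise ValueError("all-zero rows are undefined under Bray-Curtis")
    # scipy's braycurtis is sum|u-v| / sum(u+v) == 1 - 2*sum(min)/sum(u+v)
    # for non-negative data
    return squareform(pdist(values, metric="braycurtis"))


def cluster_regions(
    dissim: np.ndarray,
    linkage_method: str = "upgma",
    k: int | None = None,
    cut_height: float | None = None,
    sites: list[tuple[int, int]] | None = None,
) -> RegionClassification:
    """Agglomerative clustering of a site dissimilarity matrix.

    Exactly one of ``k`` (number of regions) or ``cut_height``
    (Bray–Curtis merge height) selects the cut.
    """
    if linkage_method not in _LINKAGE_METHODS:
        raise ValueError(
            f"linkage must be one of {sorted(_LINKAGE_METHODS)}, "
            f"got {linkage_method!r}"
        )
    if (k is None) == (cut_height is None):
        raise ValueError("specify exactly one of k or cut_height")
    dissim = np.asarray(dissim, dtype=float)
    n = dissim.shape[0]
    if dissim.shape != (n, n) or not np.allclose(dissim, dissim.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if sites is None:
        sites = [(0, i) for i in range(n)]
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method=_LINKAGE_METHODS[linkage_method])
    max_height = Z[:, 2].max() if len(Z) else 0.0
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError(f"k must lie in [1, {n}], got {k}")
        labels = cut_tree(Z, n_clusters=k).ravel() + 1
        cut = {"k": int(k)}
    else:
        if not (0 <= cut_height <= max_height):
            raise ValueError(
                f"cut_height must lie in [0, {max_height}], got {cut_height}"
            )
        labels = fcluster(Z, t=cut_height, criterion="distance")
        cut = {"cut_height": float(cut_height)}
    return RegionClassification(
        sites=list(sites), labels=np.asarray(labels, dtype=int),
        linkage_matrix=Z, linkage_method=linkage_method, cut=cut,
    )


class BioregionClassifier(BaseEstimator):
    """Estimator interface: lineage models in, region labels out.

    ``fit(models)`` aggregates the models by ``factor``, computes the
    Bray–Curtis matrix with model values as abundances, clusters it
    under the chosen linkage, and cuts the tree into regions.  Fitted
    attributes: ``composition_``, ``dissimilarity_``, ``classification_``
    and ``labels_`` (one region id per site).
    """

    def __init__(self, factor: int = 20, linkage_method: str = "upgma",
                 k: int | None = None, cut_height: float | None = None):
        self.factor = factor
        self.linkage_method = linkage_method
        self.k = k
        self.cut_height = cut_height

    def fit(self, models: dict[str, Grid] | list[Grid]):
        self.composition_ = build_composition(models, factor=self.factor)
        self.dissimilarity_ = bray_curtis(self.composition_)
        self.classification_ = cluster_regions(
            self.dissimilarity_, linkage_method=self.linkage_method,
            k=self.k, cut_height=self.cut_height,
            sites=self.composition_.sites,
        )
        self.labels_ = self.classification_.labels
        return self

    def fit_predict(self, models: dict[str, Grid] | list[Grid]) -> np.ndarray:
        return self.fit(models).labels_
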