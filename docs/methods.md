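# Methods

This note documents the models implemented in `lineagemaps`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test fixtures do and do not
demonstrate about real data.

## Data model

All rasters are `Grid` objects: a 2-D float array, the map coordinates
of the outer top-left corner, a square cell size, and a boolean nodata
mask. Coordinates are planar; cost distances use `cell_size` as opaque
map units with no latitude correction, so users working on geographic
(degree) grids either accept that distortion or supply projected
rasters. Rectangular-cell rasters are rejected rather than silently
resampled. Point records snap to cells under half-open intervals
`[edge, edge + cell_size)` per axis (for y, the numerically lower edge
belongs to the cell), so boundary points are deterministic; out-of-extent
records are reported, never dropped.

## Cost distance

Suitability `s` maps to per-cell traversal cost `-ln(max(s, floor))`
with `floor = 1e-6` by default; the floor exists only to keep the cost
of zero-suitability cells finite. A separate `impassable_threshold`
(default: equal to `floor`) controls which cells are excluded from the
graph entirely — whether zero-suitability habitat should be crossable
at high cost or strictly impassable is not decidable from first
principles, so both behaviours are exposed. Distances are multi-source
shortest paths on the 8-connected grid graph with edge weight
`mean(cost_a, cost_b) × step × cell_size` (step 1 for rook moves, √2
for diagonals) — the conventional GIS cost-distance semantics, chosen
for comparability with established implementations. Unreachable cells
carry an explicit `+inf`, never a magic number. Tests verify exact
agreement with a hand-written explicit-edge-list Dijkstra and with
scikit-image's geometric MCP on random grids.

## Lineage distribution models

The partition weight of lineage *l* at cell *c* is
`w_l(c) = max(d_l(c), d0)^-exponent` with `exponent = 2`: *inverse*
square weighting. (A literal proportional-to-d² reading would hand
distant lineages the largest share, inverting the founding assumption
that unsampled sites most likely belong to the closest connected
lineage.) The exponent is configurable.

Zero-distance regularisation was genuinely open and is handled in two
parts:

- A lineage at *exactly* zero cost distance (the cell holds one of its
  records, or connects to one through perfect-suitability habitat)
  takes the cell exclusively; several zero-distance lineages split it
  equally. This keeps the one-lineage-per-cell limit exact: a source
  cell belongs fully to its own lineage.
- Strictly positive distances are floored at `d0 = 0.5 × cell_size`
  before inversion so weights stay bounded. `d0` is a documented
  parameter of this implementation, not a claim about any original
  script.

Lineages with infinite distance get weight zero. Cells where *no*
lineage is reachable keep their suitability unallocated (all lineage
layers zero) and are counted in a report — assigning them would
fabricate range. At every other cell the lineage layers sum to the SDM
to better than 1e-9 by construction (the weights are normalised before
multiplying the suitability).

Model values below `min_value = 0.01` are zeroed *after* fitting
(`apply_min_value`): tiny values otherwise smear over wide areas. The
filter runs before any endemism calculation and endemism denominators
use the post-filter totals, which keeps each lineage's normalised MWE
mass exactly 1. The ordering of filter and normalisation was an open
choice; this one preserves the headline mass invariant exactly.

## Endemism metrics

MWE normalises each model by its own map total and sums:
`MWE(c) = Σ_l m_l(c) / Σ_c' m_l(c')`. The whole-map MWE sum therefore
equals the number of contributing models; models with zero total are
dropped with a warning. Richness sums raw suitabilities (probabilistic
richness, not a count); because lineage layers sum to the species
layer, lineage richness equals species richness. Classical WE needs a
presence threshold (default 0.01, mirroring the LDM exclusion) because
it operates on binary ranges; MWE is the primary metric precisely
because it avoids thresholding. The lineage-minus-species difference
map is computed MWE-vs-MWE, treating each species SDM as a single
"model" — a symmetric definition that reduces to zero when every
species has one lineage.

## Bioregionalization

Lineage models are block-summed by an aggregation factor (e.g. 20 to
take a 0.01° grid to 0.2°); coarse cells with any nonzero value become
sites with summed model values as abundances. Bray–Curtis
(`1 − 2Σmin/(Σ+Σ)`) is computed via `scipy.spatial.distance` and
cross-checked in tests against a naive double loop. Linkage defaults
to UPGMA (average) — the linkage used by common biodiversity tools and
a reasonable default where none is prescribed — with complete and Ward
available; the choice is recorded in output provenance. The number of
regions is a user decision: both `k` and `cut_height` cuts are
supported. Sites are always ordered row-major before clustering, which
makes agglomeration ties deterministic across platforms. The dendrogram
exports to Newick with branch lengths equal to merge-height differences.

## Habitat stability

Inputs are a `GridStack`: geometrically identical suitability slices
ordered most-recent-first with strictly increasing ages in ka. The
packaged default age schedule is 62 slices — present back to the LGM
(22 ka) in 1 ka steps, 2 ka steps to 80 ka, 4 ka steps to the last
interglacial (120 ka).

**Static stability** per cell is the exponent of the summed log
suitabilities (slices floored at `floor`). Two aggregations are
offered: `product` (the literal exponentiated sum, `Π s_t`) and
`geometric_mean` (its T-th root, the default). A raw 62-slice product
drives almost every cell toward zero and compresses rank contrast; the
geometric mean preserves the same [0, 1] endpoints (all-suitable → 1,
ever-unsuitable → ~0) and ordering while remaining interpretable as a
per-slice value. Neither is claimed to be bit-identical to any earlier
implementation.

**Dynamic stability** formalises the shifting-refugium idea — a cell is
stable if habitat persisted *in* it or could disperse *to* it. A cell's
score is the best attainable by any space-time path ending at that cell
in the present: the path occupies one cell per slice, scores each slice
with the occupied cell's suitability, and may move between consecutive
slices only while the least-cost distance (cost `-ln s` on the
destination slice, configurable to source or mean) stays within the
budget `speed × Δt × cost_calibration`. The recurrence, iterated oldest
→ present in log space, is

```
L_oldest(c) = ln s_oldest(c)
L_t(c)      = ln s_t(c) + max{ L_{t+1}(c') : LCD_t(c', c) ≤ budget }
```

(the stationary option `c' = c` is always available), and stability is
`exp(L_0)` or `exp(L_0 / T)` under the chosen aggregation. This
formulation has the properties the model is meant to have, and the test
suite asserts them: at `speed = 0` it reduces *exactly* to static
stability (only the stationary path exists); it is cellwise ≥ static
for every speed (dispersal adds options, never removes them); it is
non-decreasing in speed; and on a drifting habitat peak the cells along
the track score far above static. An alternative formulation that caps
each slice's effective suitability at the cell's own value
(`D_t = min(s_t, max-reachable D_{t+1})`) was considered and rejected:
any per-slice value bounded by local suitability forces dynamic ≤
static under a common aggregation, which contradicts all of the above
and erases the shifting-refugium signal entirely. One consequence of
the path formulation worth knowing: on a time-constant but spatially
varying landscape, a cell within budget of strictly better habitat
scores above its static value — colonisation credit from a persistent
neighbouring refugium — whereas on spatially uniform landscapes dynamic
and static coincide for every speed.

The dispersal budget is expressed in cost-distance units (map units
weighted by `-ln s`): movement through perfect habitat is nearly free,
and unsuitable habitat consumes the budget quickly. How the nominal
speed (default 10 map units yr⁻¹, the literature's median rainforest
expansion rate) couples to those units is the largest fidelity risk in
the module and is exposed as the explicit `cost_calibration` scalar
(default 1 cost unit per map unit).

The per-transition reachability step is computed by budget-limited
Dijkstra from every candidate cell (chunked; symmetric graph), which is
exact. Runtime is O(slices × N × Dijkstra(N)) and is intended for the
raster sizes of regional analyses at coarse resolution; tests and the
acceptance runs use 1×50 and 30×30 grids with 10 slices, where a full
analysis completes in seconds.

## Synthetic data

Generators are pure functions of (spec, seed) using
`numpy.random.default_rng`, so fixtures are bit-stable across runs.
Landscapes compose Gaussian patches, ridges and hard zero barriers,
clipped to [0, 1] — emulating island-like mesic habitat in a drier
matrix. Lineage points are placed by farthest-point spreading of
centres over eligible (suitability ≥ 0.2) cells with records sampled
near each centre, plus unlabelled species-only records; time series
translate the features across the grid at a fixed drift per slice.
Default fixture scale is 60×60 cells, 2–6 lineages, 10 slices — large
enough for barriers and drift to matter, small enough for brute-force
oracles to verify every component exactly.

What passing tests show: the partition conserves the species model,
masses and limits behave as derived, and the implementations agree with
independent oracles. What they do not show: that any particular real
landscape satisfies the model's assumptions — lineages sharing the
species niche, suitability rasters free of sampling bias, or paleo
hindcasts faithful to actual climate history. The generators make no
attempt at statistically realistic climate or species-accumulation
structure.

The packaged inventory fixture transcribes the published per-genus
table of rainforest-specialist lizard and frog lineages of eastern
Australia (13 genera). Its printed Total row (53 species, 102 lineages,
8703 records) matches the column sums for species and lineages exactly;
the per-genus record counts, however, sum to 7983, not 8703. The
fixture reproduces both the rows and the printed totals verbatim and
exposes them separately rather than silently reconciling the
discrepancy.

## Known limitations

- Planar geometry: degree grids incur latitude distortion in all
  distances.
- The LDM assumes lineages share the species niche; it cannot express
  niche differentiation between lineages, and offers no continuum
  toward independent per-lineage niche models.
- Unallocated cells (no lineage reachable) depend on the
  `impassable_threshold`; with a permissive threshold, distant lineages
  acquire small weights over huge areas, which is what `min_value`
  filtering is for.
- Dynamic stability's budget-in-cost-units coupling is a modelling
  choice, not a measurement; sensitivity to `cost_calibration` should
  be checked in any application.
- All-pairs reachability makes dynamic stability quadratic in cell
  count per transition; continental grids at fine resolution would need
  a tiling or pruning strategy not implemented here.
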