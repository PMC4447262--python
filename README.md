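# lineagemaps

Tools for estimating the geographic ranges of intraspecific lineages and
analysing the spatial patterns they imply — endemism, compositional
turnover, and the late-Pleistocene stability of the habitat that shaped
them.

## The problem

Phylogeographic sampling is sparse: for a typical species there are many
occurrence records but only a handful of sequenced specimens that reveal
which deeply divergent mtDNA lineage lives where. Drawing hard polygon
boundaries between lineages through these sampling gaps invents
precision exactly where the data are weakest. `lineagemaps` instead
partitions a species distribution model (SDM) probabilistically among
its lineages, producing one **lineage distribution model (LDM)** raster
per lineage that sums, cell by cell, to the species model.

The partition assumes an unsampled site most likely belongs to the
lineage best *connected* to it through suitable habitat. For lineage
*l* and cell *c*, let `d_l(c)` be the least-cost distance from *c* to
the nearest sequenced record of *l*, accumulated over the grid with
per-cell cost `-ln(suitability)` so unsuitable habitat acts as a
barrier. Then

```
LDM_l(c) = SDM(c) · d_l(c)^-2 / Σ_k d_k(c)^-2
```

i.e. inverse-square distance weights, renormalised so the lineage
layers exactly partition the species suitability. Downstream the
package provides:

- **Model-weighted endemism (MWE)**: `MWE(c) = Σ_l LDM_l(c) / Σ_c' LDM_l(c')`
  — each lineage contributes total mass 1 spread over its range, so
  cells holding a large share of one or more lineage ranges score high.
  Also model-weighted richness (summed suitability), classical weighted
  endemism (`Σ 1/range size`), and lineage-minus-species difference maps.
- **Bioregionalization**: LDMs aggregated to coarse cells, Bray–Curtis
  dissimilarity with model values as abundances, UPGMA (or other
  linkage) clustering, Newick dendrogram export.
- **Habitat stability** over a stack of time-sliced suitability
  hindcasts: *static* stability (exponentiated summed log suitability
  per cell) and *dynamic* shifting-refugia stability, in which habitat
  may persist by tracking its climate within a dispersal budget
  (default 10 map units yr⁻¹) priced in least-cost distance.
- **Synthetic data generators** for all of the above, so the entire
  pipeline is testable without any download.

## Worked example

```python
import numpy as np
import lineagemaps as lm

# a synthetic landscape: two habitat patches split by a barrier column
spec = lm.LandscapeSpec(shape=(40, 40), features=(
    lm.GaussianPatch(center=(10, 8), sd=5),
    lm.GaussianPatch(center=(30, 32), sd=5),
    lm.Barrier(axis="col", index=20),
))
sdm = lm.make_landscape(spec)
occ = lm.make_lineage_points(sdm, n_lineages=2, points_per_lineage=5, seed=1)

est = lm.LineageDistributionModel(species="sp1").fit(sdm, occ)
total = est.model_set_raw_.total()   # per-cell sum of the lineage layers
print("lineages:", est.lineages_)
print("max |Σ LDM - SDM|:",
      np.abs(total - sdm.values)[~est.unallocated_mask_].max())

mwe = lm.model_weighted_endemism(est.models_)
print("MWE map total:", mwe.grid.values.sum())
```

prints

```
lineages: ['lin1', 'lin2']
max |Σ LDM - SDM|: 0.0
MWE map total: 2.0
```

The lineage layers reproduce the species model exactly wherever at
least one lineage is reachable (the barrier isolates a few cells, which
are reported rather than silently assigned), and the whole-map MWE
equals the number of lineage models because each contributes unit mass.

The same operations are available from the shell:

```
lineagemaps synth --out-dir data --n-lineages 2 --n-slices 10
lineagemaps ldm --sdm data/landscape.tif --occurrences data/occurrences.csv \
    --species sp1 --out-dir models
lineagemaps endemism --models models --metric mwe --out mwe.tif
lineagemaps regions --models models --factor 8 --k 2 --out-prefix regions/run1
lineagemaps stability --manifest data/manifest.csv --mode dynamic \
    --speed 0.02 --out stability.tif
```

Every subcommand writes a JSON provenance sidecar (resolved parameters,
SHA-256 input digests) next to its outputs.

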