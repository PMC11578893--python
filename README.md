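# organaxis

Continuous common coordinate frameworks (CCFs) for annotated tissue
sections, with cross-modality label transfer and axis-based spatial
statistics. The package is aimed at spatial-omics analysts who have
discrete histology annotations (e.g. thymic cortex, medulla and capsule)
and want a *continuous*, scale- and rotation-invariant coordinate that
makes unpaired sections, donors and technologies (sequencing-based spots,
imaging-based segmented nuclei) directly comparable.

## The model

Discrete annotations are first moved onto a quasi-hexagonal lattice of
pitch *r* (default 15 μm): points spaced *r* in x and y with every other
row offset by *r*/2, clipped to the tissue mask. Each lattice point carries
the annotation class under it and, per class *c*, the mean Euclidean
distance *d_c* to its *k* nearest lattice points of that class (*k* = 10
for broad compartments, *k* = 1 for fine structures).

For a pair of landmark classes (A, B), the signed boundary metric is

    H(d_A, d_B) = tanh( β · (d_A − d_B) / C )

which is 0 on the A/B boundary, negative toward A, positive toward B,
bounded in (−1, 1) and steepest at the boundary. The normalization length
*C* is resolved per sample as the 95th percentile of |d_A − d_B|, making
the axis independent of tissue size, raster resolution and orientation.
A composite organ axis is a convex combination of H components; the thymic
**cortico-medullary axis (CMA)** preset is

    CMA = 0.2 · H(edge → cortex) + 0.8 · H(cortex → medulla)

running from −1 at the capsule to +1 in the deep medulla, and is
discretized into ten named anatomical levels (capsular … medullary level
3) with shared cutoffs. Axis values, H components and structure distances
(e.g. distance to the nearest Hassall's corpuscle, 350 μm default cutoff)
are transferred to observations by nearest-neighbour mapping.

On top of the axis, the package provides: KNN label transfer from a
high-dimensional reference to a low-dimensional query through a bridged,
log-normalized, z-scored shared feature space (majority vote with an
evidence fraction KNNf; neighbour-mean imputation of absent features; an
optional lineage-restricted second pass), spot QC, abundance-weighted mean
axis positions, binned expression profiles with Ward clustering, cosine
similarity and type-II two-way ANOVA, a χ² specialization-gene screen, and
a PC–axis Spearman score attributing transcriptome variance to the axis.
A parametric synthetic-lobule generator with known ground-truth radial
depth makes every step testable without external data.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from organaxis import (
    LobuleSpec, make_lobule_raster, sample_observations,
    build_hex_grid, transfer_raster_to_grid, class_distance_field,
    cma_params, compute_axis_field, bin_axis, map_to_observations,
)

spec = LobuleSpec(hc_discs=((440.0, 480.0, 40.0),), seed=0)
lob = make_lobule_raster(spec)                       # concentric lobule raster
grid = build_hex_grid(lob.broad.tissue_mask(), 15.0, ppm=spec.ppm)
transfer_raster_to_grid(lob.broad, grid, "broad")
for cls in ("edge", "cortex", "medulla"):
    class_distance_field(grid, "broad", cls, k=10)
field = bin_axis(compute_axis_field(grid, cma_params()))

obs = sample_observations(lob, 1000, noise_sigma=0.05, seed=1)
mapped = map_to_observations(field, obs.obsm["spatial"])
print(f"grid points: {len(grid)}")
print(f"axis range: [{np.nanmin(field.axis):.3f}, {np.nanmax(field.axis):.3f}]")
rho = spearmanr(mapped["axis"], obs.obs["depth"]).statistic
print(f"Spearman(CMA, true depth): {rho:.3f}")
```

prints

```
grid points: 2698
axis range: [-0.648, 0.740]
Spearman(CMA, true depth): 0.998
```

i.e. the 15-μm lattice over an ~880 μm lobule has 2,698 points, the
composite axis spans the capsule-negative to medulla-positive range
(saturation to ±1 would only occur far from every boundary), and the
recovered coordinate is almost perfectly rank-correlated with the true
normalized radial depth. The first mapped observations look like

```
    axis  H_edge_cortex  H_cortex_medulla       axis_bin
0  0.124          0.731            -0.028  medullary_cmj
1 -0.517          0.173            -0.689     cortical_2
```

— an observation with H(cortex→medulla) ≈ 0 sits on the cortico-medullary
boundary and lands in a junctional bin.

The same pipeline is available from the shell:

```sh
organaxis simulate lobule --out lob/
organaxis simulate obs --lobule lob/ --n 1000 --out obs.tsv
organaxis grid --mask lob/broad.tif --out grid.tsv
organaxis axis --grid grid.tsv --obs obs.tsv --out obs_axis.tsv
organaxis transfer --query q.tsv --ref ref.tsv --bridge bridge.tsv --k 30 --out labels.tsv
```

Every command writes a `*.provenance.json` (config hash, seed, versions)
next to its output; identical config and seed give byte-identical tables.

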