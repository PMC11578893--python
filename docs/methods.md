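# Methods

## The axis model

The coordinate is built in three stages.

**Annotation lattice.** Pixel annotations are transferred to a staggered
point lattice: rows `spacing_r` μm apart, points `spacing_r` apart within
a row, odd rows offset by `spacing_r/2`, keeping points whose center falls
on tissue. The lattice origin is anchored at the center of the raster's
top-left pixel, rows are indexed from 0 and odd rows shift +r/2 in x; the
stagger convention itself admits several parameterizations, and fixing
this one makes grids bit-reproducible. Coordinates are continuous μm with
the image convention (origin top-left, y downward); pixel (i, j) has its
center at ((j + 0.5)/ppm, (i + 0.5)/ppm). Working on a lattice of fixed
physical pitch — rather than on raw pixels — decouples all later distance
computations from raster resolution. The default pitch is 15 μm, a
compromise between spot-scale resolution and grid size.

**Distance fields.** For level ℓ and class c, each point receives the mean
Euclidean distance to its k nearest lattice points carrying c. A point
carrying c is its own nearest member, so interior points have small but
meaningful distances that still grade with position; k = 10 (broad
compartments) averages out boundary pixelation, while k = 1 is used for
small discrete structures. If a class has fewer than k members the whole
field is undefined (NaN): a mean over fewer neighbours would silently
change the metric's scale. NaNs propagate through H, the composite axis
and binning, and are excluded from every downstream statistic; the number
of undefined points is logged.

**Signed boundary metric and composition.** For a landmark pair (A, B),

    H = tanh(β (d_A − d_B) / C),      β > 0, C > 0.

This form is signed, normalized to (−1, 1), antisymmetric in (d_A, d_B),
zero exactly on the boundary d_A = d_B, and — because tanh has maximal
slope at 0 — most sensitive to displacements near the boundary. A pure
ratio form such as (d_A − d_B)/(d_A + d_B) would saturate to ±1 in region
interiors and flatten the intra-region gradient that the graded anatomical
levels require; the tanh form preserves it. β defaults to 1: with the
auto-resolved C below, β only rescales the percentile and one knob
suffices. C defaults to the per-sample 95th percentile of |d_A − d_B|
(parameter `auto_percentile`), which is what makes the axis invariant to
tissue size, raster rescaling and rotation; a fixed C in μm can be given
instead when cross-sample comparability of the *raw* H values matters
more than invariance.

The composite axis is a convex combination Σ wᵢ Hᵢ; the thymic preset is
0.2·H(edge→cortex) + 0.8·H(cortex→medulla), negative at the capsule and
positive in the deep medulla (the orientation is a convention; the
literature does not fix one). Any undefined component makes the composite
undefined rather than re-weighting the rest — partial re-weighting would
silently distort the axis on lobule fragments that lack a compartment,
which are better removed.

**Binning.** The axis is discretized with shared cutoffs into ten ordered
levels (capsular, subcapsular, three cortical levels, cortical/medullary
junctional levels, three medullary levels). The capsular and subcapsular
cutoffs sit in the negative-saturated range (−0.95, −0.8) and the
remaining eight bins split the rest of the range in equal 0.225
increments. The exact published cutoff values are not available, so these
are the package's defaults, overridable in the preset YAML; no test or
result depends on more than the count and ordering.

**Mapping to observations.** Observations take all values of their single
nearest lattice point; ties (within 1e−9 μm) go to the lowest point index
so the mapping is deterministic. Distance to a discrete structure (e.g. a
Hassall's corpuscle) is computed directly per observation as the exact
Euclidean distance to the nearest class pixel center, zero inside the
structure, with observations beyond a cutoff (default 350 μm) flagged for
exclusion.

## Label transfer

The shared feature space between query and reference is defined by a
one-to-one bridge table (e.g. protein ↔ gene names), log(1+x)-transformed
and z-scored per feature *within each object* (population variance;
constant features are zeroed with a warning — leaving them NaN would
poison every distance). Neighbours are Euclidean k-nearest in that space;
the assigned label is the majority vote, its evidence fraction
KNNf = (votes for winner)/k, and vote ties break lexicographically by
label name (logged). Absent features and continuous annotations
(e.g. pseudotime) are imputed as the unweighted neighbour mean, skipping
undefined neighbour values. Defaults are k = 30 against a transcriptome
reference and k = 7 against a smaller joint RNA/protein reference. An
optional per-sample mean-centering of the query (`batch="center"`)
provides location-shift batch correction; it is a deliberate, simpler
substitute for empirical-Bayes batch adjustment and can be switched off.
A KNNf threshold (0.5 by default in the CLI contract) lets users drop
low-confidence assignments. The two-stage path re-annotates a
lineage-filtered subset against a second reference over a hybrid bridged
space, leaving all other labels untouched.

## Axis statistics

*QC* removes spots with fewer than 1,000 detected features or fewer than
25 predicted cells (strict "fewer than": boundary values are retained).
*Weighted mean position* is Σ w·x / Σ w over observations with weight ≥ a
threshold (0.2 for corrected expression, 0.5 for abundances in the CLI
examples); it is bounded by the axis range and invariant to uniform
weight rescaling. *Binned profiles* carry one datapoint per feature,
sample and bin (the per-sample mean of log-normalized expression; an
empty bin is a missing datapoint, never zero), with features kept only if
nonzero in ≥ 5% of observations in at least one bin. Profiles are
standardized across bins and clustered with Ward linkage on Euclidean
distances (SciPy's deterministic lowest-index merge on height ties);
group similarity is the cosine of the two groups' median-across-samples
bin profiles; per-feature differences are tested by type-II two-way
ANOVA (group + bin + interaction) on the per-sample-per-bin datapoints,
with Bonferroni correction applied separately per effect family across
features (the correction family is not otherwise specified; per-effect
families are the conservative reading that keeps main and interaction
tests comparable across features).

*Specialization genes*: per gene, expression is z-scored across cells;
genes with mean raw count < 1.5 are excluded; cells with scaled
expression < 0.05 leave the selection pool (the published cut-off of 0.05
does not state its scale — scaled expression is the reading consistent
with applying z-scoring first, and the knob is exposed); pool cells at or
above the pool's 95% expression quantile are selected, ties included; a
χ² test on the (selected vs not) × cell-type table over all cells, with
significance at α = 1e−50, plus a unique maximal positive standardized
residual, declares the gene specialized to that type. "Expressed in only
one type" is operationalized by the unique-max-residual rule because the
χ² statistic alone is direction-blind.

*Variance attribution*: counts are normalized to 2,500 per observation,
log1p-transformed, optionally standardized per sample (a simple stand-in
for model-based batch regression, switchable off), and decomposed by PCA
into 10 components. A covariate's score is Σᵢ |ρᵢ|·vᵢ, with ρᵢ the
Spearman correlation of PC i with the covariate and vᵢ the component's
explained-variance percentage; the residual "other" share is floored at
zero. The summed (not multiplied) combination is used because the target
readout is a stacked per-PC decomposition; Spearman makes the score
invariant to monotone transformations of the covariate.

*Hypercluster assignment*: per cluster, spots above the cluster's 95th
abundance percentile (falling back to ties when nothing exceeds it) give
the abundance-weighted mean axis value, assigned to all the cluster's
cells.

## Synthetic data

The generator emulates an annotated lobule as concentric regions —
medulla core (200 μm), cortex annulus (400 μm), capsule/edge ring
(440 μm) at the study's annotation scale of 2 μm per pixel (ppm = 0.5) —
optionally elliptically stretched and rotated, with smooth seeded boundary
jitter (Gaussian noise field, σ in pixels) and Hassall's-corpuscle discs
nested in the medulla. Ground truth is the normalized radial depth
(0 capsule, 1 center). Observations are uniform over tissue; features
follow identity/linear/sigmoid/constant links of depth with Gaussian noise
or Poisson counts on exp(link). Transfer fixtures place one-hot Gaussian
clusters in a bridged shared space with a prescribed separation in noise-σ
units; planted specialization genes use fully exclusive constant
expression (every cell of one type at a fixed count, zero elsewhere), the
regime in which exclusivity detection at α = 1e−50 is well-posed at
300-cell scale.

What the synthetic data does *not* model: irregular lobule shapes, spatial
autocorrelation beyond the radial gradient, realistic staining texture,
segmentation errors, compositional (multi-cell spot) mixing and
empirical-Bayes-scale batch structure. Passing tests therefore demonstrate
correctness of the geometry, metric, transfer and statistical machinery
under controlled conditions — not robustness to every artefact of real
sections.

## Numerical choices and problem sizes

Distances use exact KD-trees, not raster distance transforms. NaN is the
undefined sentinel throughout. tanh saturates to ±1 in float64 for
|argument| ≳ 19; tests assert strict |H| < 1 only below that. The
invariance checks compare matched points between two independently
rasterized, gridded and normalized fields; nearest-lattice-point lookup
carries O(pitch) quantization noise per point, so invariance is asserted
on the mean absolute matched-point difference (< 0.02 under 2× raster
rescale and 37° rotation of an elliptical lobule). Suite problem sizes —
~2,700-point grids, 500–2,000 observations, 2,000 ANOVA null replicates,
300-cell specialization designs — were chosen as the smallest sizes at
which the tested properties are statistically stable; all randomness is
seeded, and Hypothesis property tests run derandomized.

## Known limitations

Only 2D sections are supported (the formulation extends to 3D). The exact
algebraic form of the published boundary metric and the published bin
cutoffs were not available; the tanh form and equal-increment cutoffs
above are this package's own, documented defaults. Label transfer operates
on standardized features directly, not on a reduced embedding. Per-lobule
axis normalization variants, probabilistic label transfer and
differential-abundance testing are out of scope.
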