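# Methods

## Overview

`voxatlas` builds voxel-scale 3D cell-type density atlases for a mouse-like
brain from spatially registered single-cell data (MERFISH-style per-cell
tables), and converts transcriptomic-type (t-type) densities into
morphological / electrophysiological (m-, e-, me-) type densities through a
probabilistic cross-modal map estimated from patch-seq-like data. Every
stage is closed over a synthetic-brain generator with known ground truth,
so each estimator can be checked for recovery.

## Region ontology and annotation volumes

The ontology is a tree in the Allen structure-graph JSON dialect (`id`,
`acronym`, `name`, `parent_structure_id`, nested `children`). A *leaf
region* is a node without children; after extension every annotated voxel
resolves to exactly one leaf. `extend_hierarchy` appends new leaf layers
under named parents — the intended use is adding granular, molecular and
Purkinje layers under each cerebellar lobule and a glomerular layer under
the olfactory bulb. Voxel indices are 0-based; world coordinates are voxel
centers in µm with x the anterior→posterior (coronal) axis, y
dorsal→ventral, z left→right, recorded in volume metadata. Volume I/O is
NIfTI via nibabel, with the voxel pitch stored in the affine.

Cell reassignment for split parents is driven by a rule table that is data
(YAML-serializable), not code: ordered predicates over the cell's class and
subclass/t-type strings, first match wins. The default table encodes:
Purkinje layer ← all Purkinje cells, all Bergmann glia, and an equal share
of microglia; molecular layer ← purely inhibitory (no Purkinje, Bergmann,
or glutamatergic cells); granular layer ← every remaining type, with Golgi
the only GABAergic type; the olfactory glomerular layer inherits all cells
of its unassigned parent. The equal microglia share is implemented as a
seeded shuffle followed by round-robin assignment: counts divisible by
three split exactly, and the remainder lands on uniformly random layers.
Cells no rule can place are flagged `unassigned`, kept in the table, and
excluded from densities.

White-matter substructures annotated only at the parent level are treated
as homogeneous: `inherit_white_matter` copies the parent's density row to
all its leaves verbatim (N/A stays N/A; zero stays zero).

## Section registration

Cutting geometry has four parameters: axial angle (rotation of the plane
normal about the dorsoventral axis), vertical angle (rotation about the
left-right axis), coronal position (µm along x), and section thickness
(default 10 µm, the fresh-frozen section thickness). Registration scores a
candidate plane by normalized mutual information between the 2D section
and the template resampled along that plane. Among the several NMI
normalizations in use we take `2·I(A;B)/(H(A)+H(B))`, which is symmetric
and bounded in [0, 1]. Histograms use fixed equal-width bins (default 64)
over each image's own range — deterministic and seedless; NMI is therefore
invariant under increasing affine intensity maps but not under arbitrary
nonlinear ones. A constant image has zero entropy; its score is defined as
0 with a warning.

Search is an exhaustive grid (defaults: axial ±45° step 0.5°, vertical
±10° step 0.25°, position step one voxel), no gradient refinement —
reproducible and free of local-optimum concerns at the cost of runtime.
Ties are broken toward the smallest (|axial|, |vertical|, position)
lexicographically. Resampling uses nearest-neighbor interpolation for
label volumes (region ids cannot be averaged) and trilinear for
intensities; out-of-volume pixels are 0. A section generated from the
template at grid-aligned geometry is recovered exactly (self-registration
identity, asserted in tests).

## Density estimation and N/A semantics

For each (leaf region, t-type):

    density = Σ_sections count(region, type, section)
              / Σ_sections volume(region, section)   [cells/mm³]

where the per-section region volume is pixel count in the cutting plane ×
pixel area × thickness. A region never intersected by a section is N/A
(NaN in matrices and volumes, empty string in CSV) — deliberately distinct
from an observed zero, which carries biological information. Every
transform preserves this distinction; taxonomy aggregation yields N/A only
when all members are N/A, so density additivity holds across levels.

QC removes cells failing upstream quality control and cells with any
coordinate exactly 0 (a known registration failure mode), plus cells
outside the volume when bounds are supplied.

Whole-region cell counts used by scaling are density × *total* region
volume from the full annotation; the sampled-slice volume appears only in
the density denominator.

## Scaling methods

**Global scaling.** Regions are grouped by named ancestor acronyms
(defaults: cerebral cortex, cerebellum, rest). Within each group one
multiplier drives the group's neuron count to its literature target
(defaults 12,618,420 / 41,825,100 / 16,446,480 neurons, summing to 70.89
million), preserving within-group ratios exactly. Cerebellar exception:
the multiplier applies to excitatory types in granular-layer leaves only,
while inhibitory and modulatory neuron numbers are held constant and
subtracted from the target first; if the group has no granular-layer
leaves the multiplier falls back to all excitatory types in the group. A
second stage scales non-neuronal types with a single brain-wide multiplier
so the all-cells total meets its target (default 108.69 million). We use
one non-neuronal multiplier brain-wide rather than one per cerebellar
layer: the quantity being calibrated (the all-cells total) is global, and
a single factor keeps all non-neuronal ratios intact. The procedure is a
projection: applying it twice is the identity, asserted to 1e-9 relative.

**Density transplantation.** Selected (region, type) densities are
overwritten with literature values and pinned. Pinned entries are excluded
from every scalable mass and their contribution is subtracted from targets
before multipliers are computed, so they survive any later scaling
bitwise. A target smaller than the pinned mass is an error, not a clip.

**Nissl-based scaling.** Per-region total density is set proportional to
mean staining intensity, anchored either at the highest-intensity region
pinned to 4×10⁶ cells/mm³ (max variant) or at the lowest-intensity region
pinned to its current density (min variant). Within each region the type
ratios are preserved. Regions without type ratios (all-N/A or all-zero
rows) are warned and left untouched rather than invented.

**Voxel granularity.** Inside a region, voxel density = region density ×
intensity / region-mean intensity, conserving the region mean by
construction. Linearity of the Nissl proxy is assumed; each type is
modulated by the same factor, so voxel-level type ratios are not
informative.

## Morphological typing

A neurite (axon, or pooled basal+apical dendrites) is summarized by its
persistence barcode under the radial-distance filtration from the soma
center (mean of soma samples): each leaf is born at its radial distance;
at a merge the component with the larger birth survives (elder rule) and
the others die at the merge point's radial distance; the root component
dies at the soma (0). Bar count equals leaf count; bars are stored as
(birth, death) with birth the component's maximal radial distance. We pool
basal and apical dendrites into one dendritic stream for pyramidal cells;
the descriptors of interest here are radial, and the pooled barcode keeps
the label space identical for both neuron classes.

Barcodes are rasterized into persistence images: one unit-mass isotropic
Gaussian per bar on a (birth, death) grid, default 100×100, σ = 1/20 of
the larger bound span, with bounds global per stream over the training set
plus a 5% margin. The unnormalized image sums to the bar count up to grid
truncation. Images are vectorized and clustered by K-means (k-means++, 10
restarts, fixed seed) — dendritic and axonal streams independently, and
pyramidal cells (PC) separately from interneurons (IN). An m-type is
`{class}_DEND_{d}_AX_{a}`; with 2 classes and 10×10 clusters the schema
spans 200 potential labels. Centroids are persisted as JSON so new
morphologies are assigned by nearest centroid (ties to the lowest index).
SWC is read by a minimal 7-column parser.

## Electrophysiological typing

E-features (measured at rheobase-percentage protocols; the synthetic
generator emits named features such as AP amplitude and ISI CV directly —
trace-level extraction is out of scope) from a reference dataset with the
11 canonical Petilla e-type labels and from patch-seq cells are pooled.
Cleaning drops all-missing rows, then any feature column with missing
values, then zero-variance features; standardization z-scores each feature
over all retained cells jointly. Agglomerative clustering (Ward linkage,
Euclidean, k = 20) assigns every cell to a feature cluster, and

    P(e_i | t_j) = Σ_k P(e_i | C_k) · P(C_k | t_j)

with P(e|C_k) estimated over reference cells in cluster k and P(C_k|t)
over patch-seq cells of t-type t; the sum runs over all 20 clusters. A
cluster containing no reference cell cannot anchor P(e|C); by default it
borrows the distribution of the nearest reference-containing cluster
(Euclidean distance between cluster feature centroids). We prefer this to
a uniform fallback because the uniform choice injects a bias that does not
shrink with patch-seq sample size — with well-separated e-types the
nearest anchored cluster is almost always the same e-type split across two
clusters, and the estimator stays consistent; `fallback="uniform"` is
available. An optional class-constraint step forces excitatory t-type rows
onto the pyramidal e-type and removes pyramidal mass from inhibitory rows
(renormalized).

## Cross-modal map and extrapolation

Patch-seq cells are aligned to reference t-types by nearest neighbor in
PCA space: both expression matrices are restricted to their common genes,
log₂(x+1)-transformed, components fit on the reference (50, or n_types−1
if smaller), query cells projected into the same embedding. Contingency
comparisons keep only native labels supported by ≥3 cells. The
zero-inflation gene selector keeps genes whose zero fraction exceeds
`exp(−decay·(µ − xoffset)) + yoffset` with defaults (0.04, 6.2, 1.2), µ
the mean log₂(count+1) over nonzero cells.

P(m|t) is the empirical conditional of m-labels given t-labels. P(me|t)
is the outer product of the m and e rows per t-type — m and e assumed
conditionally independent given t, recorded in the output metadata. This
is a first-order approximation: genuinely co-occurring (m, e) pairs are
under-weighted and rare combinations over-weighted to the extent that
residual dependence exists beyond the shared t-type.

Extrapolation to t-types without patch-seq coverage: genes are ranked by
seeded random-forest impurity importance for me-labels (top 100 kept) and
for region-of-origin (the 100 least important kept); their intersection
defines a subspace predictive of me-types but insensitive to region. In
that subspace (z-scored per gene over t-types), each uncovered t-type
averages the probability rows of its k = 10 nearest covered t-types with
inverse-distance weights `1/(d + 1e-9)`; an exact-zero distance copies the
neighbor's row. Extrapolation acts on the me rows directly (not on the m
and e factors separately), keeping extrapolated rows convex combinations
of stochastic rows. A 10-fold cross-validation harness (MSE/MAE) is
provided for tuning the gene count and k.

Me-type densities follow by linearity: per region, the me vector is the t
density vector times the row-stochastic map, conserving regional neuron
totals exactly. Validation compares regional mRNA densities
`mRNA_t = D_t·E_t` against the me route
`mRNA_me = (D_t·P)·(Pᵀ·E_t) × (N_me/N_t)²` — the squared correction
reflects the map being applied once on densities and once on expression;
with P the identity the two routes agree exactly. Relative error is
`|mRNA_t − mRNA_me| / mRNA_t`, N/A where the denominator is zero, also
summed per region and per gene.

## Composition clustering

Region × type densities are normalized to fractions (so region size does
not dominate), embedded in 2D (UMAP when available; exact PCA otherwise —
tests use PCA for determinism), and clustered with seeded K-means for
k = 1..10. We cluster in the 2D embedding (a flag allows original-space
clustering). The elbow is formalized as the k maximizing the second
difference of the WCSS curve. Two clusterings over the same regions are
compared by the overlap matrix, entry (i, j) = 100·|A_i ∩ B_j|/|A_i|,
rows summing to 100. Region profiles list types whose fraction strictly
exceeds a threshold (default 5%), sorted descending.

## Synthetic brain generator

`make_brain` builds a padded box split along the coronal axis into three
group slabs (cortex, cerebellum, rest); leaves tile each slab's
cross-section as cuboids and extend through the slab, so every coronal
section intersects several leaves. Cerebellar lobules carry
granular/molecular/Purkinje layer leaves stacked dorsoventrally; one
white-matter tract with two leaves exercises parent-level inheritance.
Defaults are desk-scale: 64×48×48 voxels at 25 µm (a 1.6×1.2×1.2 mm
block), ~20 leaf regions, 12 t-types whose taxonomy carries the marker
names the split rules key on. Per-region per-type densities are drawn
uniformly from 2,000–40,000 cells/mm³ over a class mask that mirrors the
layer rules (granular layers hold the excitatory granule type, molecular
layers are purely inhibitory, Purkinje layers hold Purkinje cells and
Bergmann glia; microglia are everywhere). The margin default (3 voxels)
makes sibling regions' voxel shares exactly equal under the default
grids. Nissl intensity is the region's total density rescaled to [0, 1]
with 8% voxel-level Gaussian noise.

`make_cells` resamples the annotation along each (optionally tilted)
section plane and draws Poisson(density × pixel area × thickness) cells
per (region, type), uniformly over the region's plane pixels with
sub-voxel jitter — so the density estimator is unbiased by construction.
It injects a configurable fraction of QC-failing cells and a few
pass-QC cells with zero coordinates to exercise the filter.

`make_patchseq` draws, per cell: a neuronal t-type, an m-archetype from
the true P(m|t) and an e-type from the true P(e|t) (row-stochastic tables
with one dominant column per row); negative-binomial expression around
per-t-type gene means with a private over-expressed gene block per type;
a parametric binary tree whose depth and segment length are set by the
m-archetype (so barcodes separate by archetype); Gaussian e-features
around per-e-type means. Reference e-cells with canonical labels are
emitted alongside. One master seed fans out to per-artifact child streams
(`np.random.default_rng([seed, stream])`), so artifacts are independently
reproducible bit-for-bit.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: optical crowding and segmentation
failure in dense layers (the very effects the scaling methods exist to
remedy), misregistration between sections and the reference, anisotropic
region shapes, realistic gene-panel structure or dropout beyond the NB
model, apical/basal dendrite asymmetry, and residual m–e dependence given
t (the generator samples m and e independently given t, matching the
map's assumption rather than stressing it).

## Problem sizes and numerical choices

Test fixtures run at the generator defaults above (≈20k–25k cells per
brain, 6–8 sections, 30–200 patch-seq cells per t-type depending on the
test); the end-to-end map-recovery check uses 200 cells per t-type, where
the estimated P(me|t) lands within total-variation 0.1 of the generating
table. Scaling identities hold to 1e-9 relative; probability rows sum to
1 ± 1e-9. Degenerate inputs are defined rather than undefined: constant
images score NMI 0, empty barcodes give zero images, all-zero composition
rows give empty profiles, empty scaling groups are skipped with warnings.

## Known limitations

- The NMI search is exhaustive; fine grids over large templates are slow
  by design (reproducibility over speed).
- The conditional-independence product map cannot represent m–e
  co-occurrence beyond t-type; see above.
- The mRNA correction `(N_me/N_t)²` is a single global calibration; it is
  meaningful for genuine reductions (N_me < N_t) and exact only for the
  identity map.
- Nissl-based totals assume intensity ∝ cell density; cell-size and
  RNA-content differences between regions violate this in real tissue.
- NRRD volumes are not read or written; NIfTI covers the volume I/O.
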