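# Methods

This note documents the models, conventions and numerical choices behind
`spotalign`, what the synthetic-cohort generator does and does not emulate,
and the known limitations of the statistical procedure it implements.

## Coordinate conventions

All spot positions are 0-based pixel coordinates `(x, y)` with x rightward
and y downward; the Space Ranger positions file's `pxl_col_in_fullres` maps
to x and `pxl_row_in_fullres` to y.  Physical calibration comes from the
known capture-spot geometry: 55 µm spot diameter and 100 µm centre-to-centre
pitch, so µm/pixel = 55 / `spot_diameter_fullres`.  After
`rescale_to_template` (default 10 µm/px) coordinates are in template pixels;
the digital-grid and registration-error computations multiply by the
template resolution to work in micrometres.

Rotation is clockwise in image coordinates: 90° maps `(x, y) → (H−1−y, x)`
for an H-row image; mirroring maps `(x, y) → (W−1−x, y)`.  Right-hemisphere
samples are mirrored into left-hemisphere space before registration so a
single template serves the whole cohort.

## QC and normalization

Spots must be flagged in-tissue and have total counts ≥ 5000 ("fewer than
5000" is removed — a spot with exactly 5000 is kept); genes with zero total
counts in a sample are dropped.  The QC floor, like every other threshold,
is surfaced in the config and recorded in the run report.

Three log2 normalizations are provided:

| scheme | formula | use |
|---|---|---|
| `log2_count1` | log2(1 + c) | raw-count proportional scale |
| `log2_cpm1` | log2(1 + 1e6·c/total) | region-DE path (rank tests) |
| `log2_size1` | log2(1 + 1e4·c/total) | digital-spot t-test path (default) |

The default for the t-test path needs justification, because the choice is
consequential.  Raw log2 counts (`log2_count1`) contain each spot's library
size; when the mean library size of the two condition groups differs by
chance — unavoidable with 6 and 7 samples — every gene shifts between
groups and the per-spot false-positive rate explodes (we measured per-spot
family-wise error up to 0.69 at a nominal 0.05 on null cohorts).
`log2_cpm1` corrects library size but puts the pseudocount on the CPM
scale, where a single count at a typical 10⁴-count spot is ~100 CPM ≈ 6.6
log2 units: the zero/nonzero gap dominates the variance of every
moderately expressed gene and sensitivity collapses.  `log2_size1` rescales
counts to a common library size of 10⁴ (the counts-per-10k convention used
across single-cell analysis) with the pseudocount back on the count scale:
library size is removed while a one-count jump stays ~1 log2 unit.  On null
cohorts this restores nominal calibration; on cohorts with planted effects
it retains the sensitivity of the raw-count scale.  The region-DE path uses
`log2_cpm1` as is conventional there: the Kruskal–Wallis test is rank-based
and indifferent to the pseudocount scale, while the reported log2 fold
changes follow the usual CPM convention.

## Registration

One best-fit sample is registered to the template; all other samples are
registered to the best fit and the transforms composed
(`[sample → bestfit, bestfit → template]`).  Registering stain-to-stain is
better conditioned than registering every histology image to an atlas
raster directly, and a defective registration of one sample cannot corrupt
the others.  The best fit may be user-specified; otherwise an advisory
score (tissue-mask IoU against the template after a moments alignment)
picks it.

Backends:

- **moments** (default): similarity transform from binary tissue masks —
  translation from centroids, rotation from the principal axis of the
  second-moment matrix, scale from √(area ratio).  The principal axis has a
  180° ambiguity; both candidates are scored by mask overlap and the better
  one kept.  This backend assumes the tissue shape is anisotropic and not
  180°-symmetric, which holds for coronal hemisphere sections (and for the
  generator's tissue shape, see below).
- **landmarks**: least-squares similarity (Umeyama) from ≥ 2 matched point
  pairs.
- **external**: imports a displacement-field raster produced by an external
  diffeomorphic tool (e.g. ANTs SyN).  Diffeomorphic registration is
  deliberately not reimplemented; the adapter declares the **forward**
  convention `p′ = p + D(p)` with bilinear interpolation, offsets in the
  same units as the coordinates, fields stored at template resolution in
  (x, y) order.  Points outside the raster are clamped to the nearest edge
  and flagged.

Registration moves coordinates only; expression matrices pass through
untouched.

## Digital spots

A honeycomb lattice at 150 µm spacing is generated inside the template
mask: rows at 150·√3/2 µm, alternate rows offset by 75 µm, so every
interior spot has 6 equidistant nearest neighbours at exactly the spacing.
The lattice phase is anchored at the centroid of the mask bounding box —
the construction has no natural origin, and the anchor makes grids
reproducible for a given mask.  A lattice point is kept when its centre
pixel lies in the mask.

Each digital spot then takes, per sample, the k = 7 nearest registered
spots within 450 µm (7 = one platform spot plus its 6 hexagonal
neighbours; 450 µm = 3 grid spacings), ties broken by (distance, spot
index).  A sample spot may serve several digital spots.  "Sufficient
neighbours" for keeping a digital spot defaults to the full k from *every*
sample — the strictest reading, which keeps pooled widths exactly k×n per
group (42 for n=6, 49 for n=7) and the t-test's degrees of freedom constant
across the grid; `min_required_per_sample` relaxes it.

## Per-spot statistics

At each kept digital spot, each gene's pooled group values are compared
with a two-tailed two-sample t-test (Student pooled-variance by default,
df = nA+nB−2; Welch selectable).  Sign convention: t > 0 means the second
group's mean is higher (call with control first).  Zero pooled variance
with equal means yields t = 0, p = 1 (identical constant values carry no
evidence); zero variance with unequal means yields ±∞ and p = 0.

The correction family is the m genes tested (the intersection of all
samples' post-QC gene lists): Šidák α_s = 1−(1−α)^(1/m), Bonferroni α/m,
or BH step-up applied per digital spot across genes.  A gene is a DEG when
at least one kept spot passes, classed *up*/*down*/*mixed* by the signs of
its significant t statistics.  Mask-restricted single-gene tests use the
number of masked spots as the family (α = 0.1 by default, the level
consistent with the published m = 140 → 0.00075 threshold).

Two caveats are inherent to this design and documented rather than fixed:

1. **Pseudoreplication.**  Pooled spots are treated as independent
   replicates within a group, although spots from one animal share
   sample-level factors.  Perfect library-size normalization removes the
   largest such factor; residual per-sample effects (e.g. the
   depth-dependent mean of the log transform) leave the per-spot
   family-wise error slightly above nominal (we measure ≈0.055 at α = 0.05
   under the generator's conditions).  A per-animal mixed model would
   address this but is out of scope.
2. **Background gene calls.**  Because the family-wise error is controlled
   *per digital spot*, a grid of S effectively independent spots yields
   ≈ α·S expected false DEGs at the gene level (a few dozen over a
   320-spot grid at α = 0.05, consistent with what we measure).  Gene-level
   claims should therefore rest on the per-gene significant-spot counts and
   effect maps, not on bare membership in the DEG list.  The experiment-wide
   alternative (correcting by genes × spots) eliminates background calls but
   collapses sensitivity, because t statistics are strongly correlated
   across spots through the shared samples.

## Region-of-interest DE

Given per-spot region labels (an input — the clustering or deconvolution
that produces them is outside this package), each gene is tested between
conditions within a region by the Kruskal–Wallis rank-sum test (two groups;
H with tie correction, p from χ² with 1 df), implemented vectorized over
genes and cross-checked against `scipy.stats.kruskal` in the tests.  The
log2 fold change is the difference of group medians on the log2(CPM+1)
scale, so a gene unexpressed in a region has log2FC exactly 0.  P-values
are BH-adjusted per region across genes; a DEG requires FDR < 0.001
(strict) and |log2FC| ≥ 0.2 (inclusive).  The 0.2 cut is adopted from the
published figure convention; note log2(1.2) ≈ 0.263, so a "1.2-fold"
phrasing of the same rule is slightly stricter.  DEG sets across regions
are summarized as exclusive-intersection counts (the UpSet decomposition);
the exclusive counts sum to the size of the union.

## Synthetic cohorts

The generator emulates the features of a multi-sample Visium experiment
that this pipeline is sensitive to:

- **Geometry**: per-sample hexagonal lattices (100 µm pitch, 55 µm spots)
  inside an asymmetric tissue shape (an ellipse with a notch removed — the
  notch breaks 180° symmetry so principal-axis registration is
  well-posed); sample images at 5 µm/px, template at 10 µm/px.
- **Misalignment**: one rigid transform per sample (rotation U(−10°, 10°),
  translation U(−200, 200) µm per axis), plus mirrored "right hemisphere"
  samples (2 by default).
- **Counts**: negative binomial, mean = libsize · base_g · 2^effect,
  dispersion (NB size) 2.0.  Per-gene baselines follow the gamma(2, 2.5)
  quantile profile over gene index (mean 5 counts/spot): marginally
  identical to gamma draws but deterministic, so a gene's expression level
  is a known function of its index and effects can be planted at chosen
  quantiles.  Library-size factors U(0.7, 1.3) per sample emulate
  sequencing-depth differences.
- **Truth**: true transforms, per-spot region labels (disk-shaped
  "hippocampus" and "cortex" regions plus background) and the planted DE
  table are returned for validation.
- **Scale**: defaults are 6 NSD + 7 SD samples, 2000 genes, ≈730 in-tissue
  spots per sample on a 3.6 × 3.2 mm extent — a full pipeline run takes
  ≈10 s, and the 20-replicate null-calibration experiment a few minutes.

Not emulated: histology texture (images are synthetic brightfield-like
rasters), cell-type mixtures, nonlinear tissue deformation, spatial
correlation of counts beyond region structure, and per-spot library-size
gradients.  Passing tests therefore demonstrate the correctness of the
geometry, bookkeeping and statistics under the stated noise model — not
robustness to deformation or segmentation artifacts in real histology.

## Numerical choices and degenerate inputs

- Otsu tissue masking operates on a 20 µm Gaussian blur; the tissue side of
  the threshold is chosen automatically as the darker side (H&E-like
  brightfield).  A constant image has no threshold and raises.
- An empty template mask yields an empty grid with a warning (not an
  error); a sample with zero registered spots, an empty landmark set, or an
  all-spots-removed QC outcome raise immediately with the sample named.
- k-NN queries use a KD-tree with the distance cap applied strictly
  (≤ 450 µm), ties broken deterministically.
- Grid generation, simulation and the pipeline are deterministic given
  their seeds/configs; reruns produce identical DEG lists.

## Desk-scale vs published scale

The published analysis used 13 real samples on the Allen CCF coronal
slice-70 raster (2052 digital spots, 1892 after coverage filtering,
m = 18,893 genes, 413 DEGs).  Those numbers require the external data and
atlas raster and are not reproduced here; the package reproduces the
*procedure* and its printed constants (thresholds 2.71e-06 and 0.00075, 6
equidistant neighbours, 42/49 pooling widths) and validates the rest by
property: null calibration, planted-effect recovery with correct direction
classes, Šidák/Bonferroni/BH set relations, exhaustive-oracle equivalence
for the combinatorial steps, and sub-30 µm registration recovery of known
rigid perturbations.  `generate_hex_grid` accepts any user-supplied mask
raster, so the atlas-based spot count can be checked externally when that
raster is available.
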