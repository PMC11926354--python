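# Methods

This note records the models, conventions and numerical choices behind
`mgmorph`, in the order the pipeline runs them, and what the synthetic
benchmarks do and do not demonstrate.

## Geometry and units

All coordinates are 0-based, origin top-left; boxes are half-open
`(x0, y0, x1, y1)` rectangles, which makes the tiling arithmetic exact.
Physical thresholds are stored in micrometres (µm, µm²) and converted to
pixels per image, so one configuration transfers across acquisition
resolutions. At the default 0.464 µm/px each pixel covers 0.215 µm².
Grayscale conversion of RGB uses fixed Rec. 601 weights
(0.299, 0.587, 0.114) so results do not depend on the image library;
staining is dark-on-light, and the inverted view `255 − gray` is used
wherever an intensity-increasing "signal" is needed.

### A/B tiling

Unit-A tiles partition the slide on a regular grid of side
`round(tile_side_um / pixel_size)` rounded to the nearest even integer
(512 px for 238 µm at 0.464 µm/px). Unit B is the same grid shifted by
(−half, −half) and clipped at the borders, never padded. Unit A claims
cells whose boxes lie strictly inside a single A tile; unit B claims
cells whose boxes cross an internal A gridline. One geometric limit is
worth stating: a box that crosses an A gridline in one axis *and*
straddles a B gridline in the other is fully contained in neither unit.
The pipeline therefore assigns each detection to the tile containing its
box centre and reads the segmentation crop from the full image around
the doubled box (capped at 119 µm), so boundary cells are segmented
whole and A/B deduplication partitions the cells exactly; residual
duplicates (mask IoU > 0.5) resolve to the higher detection score, then
the larger mask, then the lower (y, x) origin — every tie-break is
deterministic.

## Detection, segmentation, reconciliation

The detector/segmenter is a plug-in (`SegmenterBackend`): `detect(tile)`
returns scored boxes, `segment(crop, context)` returns a binary mask,
and both must be deterministic for fixed input. Detections at
probability exactly 0.5 are rejected (strict `> min_score`). Two
backends ship with the package: a classical adaptive-threshold +
Otsu backend for dark-on-light stains, and a ground-truth oracle used by
the test harness. Trained neural detectors can be wrapped behind the
same two methods without touching the rest of the pipeline.

Raw masks may contain several connected components. Reconciliation is
rule-based and conserves foreground: the largest component is the cell
body; components whose minimum Euclidean distance to the growing cell is
below 3.25 µm (7 px at default resolution) attach as processes, iterated
to a fixed point so chains of nearby fragments attach; non-attached
components above 107.65 µm² (500 px) spawn separate candidate cells; the
remainder is debris. Distances are pixel-centre distances from the
Euclidean distance transform — adequate at these thresholds without
sub-pixel machinery. Instances with mask IoU > 0.7 merge transitively
(union-find), keeping the higher detection score, so the result is
independent of processing order. Cells below 30 µm² are removed last.

## Morphometry

The 28 parameters comprise 25 classifier inputs (areas, perimeters,
spans, ratios, circularities, fractal measures), two intercellular
distances, and the focus measure. The published six-group census
(6+5+6+4+2+3) sums to 26 shape values; the registry resolves this to
exactly 25 inputs by computing but excluding `hull_span`, which is
identical to the maximum Feret diameter of a convex set. The registry
(name, group, units, classifier-input flag) is exported as a table and
embedded in the COCO extras of every annotation file.

Conventions that required a choice:

* **Soma extraction** — core = the connected region, containing the
  global maximum of the Euclidean distance transform, where distance
  ≥ 0.5 × max; the soma is that core dilated by the threshold radius,
  constrained to the mask. Parameter-free and deterministic; on a solid
  disk it recovers essentially the whole disk, on a branched cell a
  compact body. On thin rods the whole body reads as soma, which is
  acceptable because rod classes are separated by span ratios, not soma
  fraction.
* **Perimeters** are polygonal marching-squares contour lengths with a
  3-point circular moving average on the vertices. Raw marching squares
  on binary input overestimates a discrete disk's perimeter by ~6%
  (circularity 0.89 instead of 1); the smoothing removes that staircase
  bias (disk circularity 0.98) while leaving straight edges untouched.
  Because cell and hull contours are estimated independently, identities
  like CPM ≥ CHPM hold only to ~1% on near-convex cells.
* **Feret spans** come from the convex hull of foreground pixel centres
  (max pairwise vertex distance; min width by rotating calipers), with
  the minimum width floored at one pixel to account for finite pixel
  extent of 1-px-wide structures.
* **Fractal dimension** is minus the least-squares slope of log N(s) vs
  log s over dyadic box sizes s ∈ {2, 4, 8, 16, 32} on the tight crop;
  masks smaller than the smallest box are flagged undefined rather than
  extrapolated. **Lacunarity** at radius r is Var(M)/E[M]² + 1 over all
  r × r gliding boxes, r ∈ {4, 8, 16, 32}; `LC`/`stdLC` are the mean and
  SD over the valid radii. A filled square gives FD = 2, LC = 1,
  stdLC = 0; a 1-px line gives FD = 1.
* **Brenner focus measure** uses lag-2 squared differences in both axes,
  each normalised per valid pixel and summed, inside the cell box scaled
  1.2× about its centre. Per-pixel normalisation makes the value
  independent of crop size, so one gate threshold (600, strict >)
  applies to all cells; a constant patch scores 0 and a unit-slope 8-bit
  ramp scores exactly 4. Both the lag and the threshold are
  configuration keys.
* **Intercellular distances** use Delaunay adjacency on soma centroids
  (k = 3 nearest neighbours when the triangulation is degenerate, both
  cells mutually adjacent at n = 2). `mDS` is the mean centroid distance
  to neighbours; `mDP` is the mean over neighbours of the minimum
  boundary-to-boundary distance, zero for touching masks, and undefined
  (NaN, not 0) for a single cell.

Per-cell failures (degenerate masks, boxes too small for the focus
window) are recorded as flags with NaN values; they never abort a slide,
and flagged rows are dropped (with a logged count) at training time.

## Classification

C5.0 itself is proprietary, so the classifier is an open C4.5-style
tree: binary numeric splits at midpoints between distinct sorted values;
candidate splits scored by information gain; among candidates with at
least the mean candidate gain, the split with the highest gain ratio
wins (ties: lower feature index, then lower threshold). Pruning is
bottom-up pessimistic-error pruning: a subtree collapses to a leaf when
the leaf's predicted errors — n times the Clopper–Pearson upper
(1 − CF) bound on the error rate, CF = 0.25 — do not exceed the
subtree's. Leaf predictions break ties in the fixed class order
R < H < B < A < RD < HR. The fitted tree serialises to JSON with its
configuration and a hash of the feature registry, and refuses to predict
cells lacking a registry feature. Random-forest and linear-discriminant
baselines are exposed behind the same fit/predict interface.

The focus gate runs before classification and quantification: cells
with FM ≤ 600 are tagged UF, excluded from analysis, and rendered gray.
Evaluation reports the 6×6 confusion matrix, per-class precision,
recall, F1 and one-vs-rest accuracy, averages weighted by truth-class
support (so weighted recall equals overall accuracy, asserted on every
report), and Cohen's kappa, which corrects for the strong prevalence
imbalance of morphotypes (ramified cells dominate healthy tissue).
Cross-validation uses seeded stratified folds; a class with fewer
members than folds stays whole in one fold with a warning.

## Detection metrics

IoU and Dice follow the usual set definitions (empty union → IoU 0;
two empty masks → Dice 1, documented). mAP50 follows COCO API
semantics — predictions matched greedily in descending score order,
each ground truth used at most once, detections pooled across images,
101-point interpolated precision — so external COCO tooling reproduces
the numbers on exported files. Segmentation mAP uses mask IoU, detection
mAP box IoU.

## Regional quantification and maps

Cells are assigned to the region under their soma centroid (processes
may cross boundaries; centroid assignment is single-valued and
deterministic); label 0 collects into an "unparcellated" bucket so
counts always conserve. Region areas come from label-raster pixel
counts × pixel area; densities are counts/area in cells/mm². The
activation score is the weighted morphotype frequency with weights 0
(R), 0.33 (H), 0.66 (B), 1 (A), 0 (RD), 0.66 (HR) — a convex
combination, hence bounded in [0, 1] and invariant under uniform count
scaling; it is undefined (NaN) for empty regions rather than 0.
Morphotype maps fill each mask with its class colour over the dimmed
source image; parameter maps use the jet colormap over the 1st–99th
percentile of the parameter (or an explicit range). 3D output linearly
interpolates per-region densities along the slice axis between measured
slices (values at a slice position reproduce that slice exactly and
interior values are bounded by their neighbours); areal densities
convert to cells/mm³ by a configurable effective thickness, since a
registration-based atlas volume normalisation is outside the package's
scope — region label rasters are an input, not a product.

## Synthetic scenes: what they emulate, and what they do not

The generator draws procedural shape families tuned to the qualitative
signatures of the six morphotypes: ramified cells are small somas with
long thin branched random-walk processes (low solidity, high FD);
hypertrophic cells have larger somas and thicker, shorter processes;
bushy cells a dense short-process halo (high solidity); ameboid cells
near-convex ellipses (circularity ≥ 0.7, soma fraction ≥ 0.8); rods are
elongated with polar processes (span ratio ≥ 3); hypertrophic rods
elongated with a thickened body. Cells are placed by rejection sampling
under a configurable overlap budget (default 0) on a light background
with per-cell staining-intensity jitter (±15%), additive Gaussian sensor
noise (σ = 5 grey levels), and optional defocus modelled as Gaussian
blur of the final image — which provably lowers the Brenner measure, so
focus-gate behaviour is testable. The default scene density (~450
cells/mm² at the default spec) sits in the middle of the range reported
for rat cortex and hippocampus (~440–1100 cells/mm² across sub-regions);
the generator accepts densities up to the top of that range. Everything
is a deterministic function of the seed.

The feature benchmark (`make_feature_benchmark`) bypasses rendering:
each class shifts one designated feature by `separation` pooled SDs in
an otherwise standard-normal 25-feature space (affinely rescaled to
realistic magnitudes, which leaves tree classifiers unaffected).
Separation 0 is exactly chance (≈ 1/6); separation 4 is essentially
separable, and five-fold accuracy ≥ 0.9 there is a parameter-recovery
check of the tree implementation, not a claim about histology.

What passing these tests shows: the geometry, reconciliation rules,
feature definitions, classifier and scoring behave exactly as specified
on inputs with known truth. What they do not show: performance on real
DAB-stained tissue, where touching cells, section artefacts, staining
gradients and genuinely ambiguous intermediate morphologies dominate the
error budget — on real slides the detector/segmenter backend and the
training labels, not this pipeline's plumbing, set the ceiling.

## Problem sizes and determinism

The test-suite and acceptance-script scenes (512–1024 px, 17–30 cells;
benchmark n = 200/class) were chosen as the smallest sizes at which
every property is stable across seeds; all quantities they print are
recomputed at run time. Two runs with the same seed and configuration
produce byte-identical COCO JSON and region tables: all iteration orders
are fixed, all tie-breaks are total orders, and JSON is written with
sorted keys.

## Known limitations

* Pyramidal slide formats (SVS/NDPI) and stitching are out of scope;
  input is a pre-stitched single-plane raster.
* Soma extraction and the mDS/mDP neighbour graph are reimplementation
  conventions; other reasonable definitions would shift absolute values
  (but not the invariances tested).
* The gain-ratio tree implements single-tree C4.5-style learning only —
  no boosting, costs, or rule sets.
* Atlas registration is not performed; region label maps must be
  supplied (or generated synthetically for testing).
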