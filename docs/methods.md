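# Methods

This note documents the models, conventions and design choices behind
`vinevigor`, in the order the pipeline runs them.

## Geodata conventions

Rasters are north-up 2-D grids with square pixels; pixel centers sit at
integer `(row, col)` and the georeference stores the world coordinates of
the center of pixel (0, 0).  Row indices increase southward.  GeoTIFF
files are written with `PixelIsPoint` semantics (the tiepoint refers to the
pixel center); files written with the more common `PixelIsArea` convention
are shifted by half a cell on read, so both round-trip correctly.  Rotation
is restricted to 0: orthomosaics are conventionally north-up, and oriented
geometry is carried by the per-vine sampling rectangles instead.  Payloads
are stored as float32; the nodata sentinel (default −9999) is preserved
through I/O.  Vine identifiers must be unique — the ground-truth join
depends on it — and duplicates are a hard error.

## Synthetic scene generator

The generator emulates a steep-slope vineyard at véraison:

- **Terrain** — an inclined plane with gradient magnitude tan(slope)
  oriented along the aspect (azimuth of steepest descent, clockwise from
  north).  Defaults: slope 30°, aspect 202.5° (SSW).
- **Planting** — rows run in the fall line; 2.0 m between rows, 1.2 m
  between vines in a row, with 3 cm Gaussian stem-position jitter.  Vines
  are numbered row by row in the along-row order.
- **Labels** — growth classes drawn from the field survey's frequency
  distribution 206/190/343/470/402/46 over classes (0, 1, 3, 5, 7, 9);
  `class_probs` is configurable (acceptance checks use a uniform mix to
  guarantee ≥ 30 vines per class).
- **Canopy geometry** — each vine is a radially tapered cap
  h(r) = H·cos²(πr/2R) with class-dependent height H (0, 0.3, 0.8, 1.3,
  1.8, 2.2 m) and radius R (0.05, 0.15, 0.30, 0.45, 0.55, 0.65 m).  The
  cap integrates in closed form to V = H·R²·(π/2 − 2/π), which is the
  analytic truth volume stored per vine (cross-checked by quadrature in the
  tests).  Overlapping canopies combine by maximum, not sum; with the
  default radii, adjacent canopies barely touch, so the per-vine truth
  remains accurate.
- **Biological variability** — per-vine multiplicative size factors
  (height CV 0.12, radius CV 0.06, both clipped) and additive per-vine leaf
  spectra jitter (SD 0.005/0.005/0.004/0.015/0.03 for blue/green/red/
  red-edge/NIR).  Without this, same-class vines would be numerically
  identical and every classifier would score 100%; the chosen CVs place
  adjacent classes roughly 2 SD apart structurally, which is what gives the
  cross-validated accuracies their realistic texture.
- **Reflectance** — each pixel is a linear mixture of a class-dependent
  leaf endmember and a soil endmember, weighted by canopy cover, plus
  optional i.i.d. Gaussian noise (default SD 0.01).  Leaf NIR/red-edge rise
  and red falls with vigour class; all pure-leaf OSAVI values exceed the
  0.7 masking threshold by construction, and soil OSAVI ≈ 0.07, so the
  threshold is meaningful on defaults.  Canopy *height* tapers smoothly,
  but canopy *cover* is modeled as an opaque disk of radius 0.9 R: a
  crown's leaf-area edge is abrupt even where its height profile is not,
  and this keeps the canopy/soil mixture bimodal the way real
  high-resolution orthomosaics are.  The truth canopy raster is that disk
  (cover ≥ 0.5).
- **Saturation and interrow vegetation** — `nir_saturation_level` caps the
  NIR band before noise, emulating the optical saturation of dense
  canopies: the top three classes become spectrally confusable while their
  heights remain distinct, which is how the structural-over-spectral
  feature-group ordering is reproduced.  `interrow_vegetation_fraction`
  paints low (≤ 0.1 m), high-OSAVI grass patches between rows, the real
  confusion source for the weakest classes.
- **Determinism** — one seed; independent sub-streams (positions, class
  draws, per-vine factors, noise, grass) are spawned from it, so scenes are
  bit-identical across runs.

What the generator does **not** emulate: shadows, BRDF, view-angle effects,
within-crown porosity, photogrammetric DSM artifacts (an optional i.i.d.
DSM noise term exists but defaults to 0), labeling error, and spatial
autocorrelation of vigour along rows.  Passing tests therefore demonstrate
the pipeline's correctness and its qualitative behavior (monotone volume
recovery, saturation-driven feature ordering), not field-level accuracy
figures.

## Spectral indices

Standard formulas on reflectance in [0, 1]; OSAVI uses the 0.16 soil
adjustment.  The TSAVI soil line (slope a, intercept b, cross term X) is
site-specific and unknown for the reference field; defaults a = 1.2,
b = 0.04, X = 0.08 are common literature values and fully configurable.
Division by zero yields nodata rather than 0, so flat-zero reflectance
artifacts stay distinguishable from a true zero index.

## GLCM texture

Bands are quantized into N equal-width bins (default N = 32) over the band
range (configurable), last bin upper-inclusive, values clamped.  Ordered
level pairs are counted at distance 1 in four directions (0°, 45°, 90°,
135°), symmetrically (each pair in both orientations), within a 3×3 moving
window; pairs touching nodata are skipped and windows without a valid pair
emit nodata, as do the border pixels whose window leaves the raster.

The eight measures use the standard Haralick definitions.  Conventions
that the literature leaves loose are fixed as follows: entropy uses the
natural logarithm (a log2 flag exists); correlation divides the GLCM
covariance by the product of the *marginal* standard deviations and is
clamped to [−1, 1] against rounding; a degenerate window (zero marginal
SD) reports correlation as nodata.  Mean and variance are the marginal
(row) mean and variance of the symmetric matrix.

Two implementations coexist deliberately: a per-window definitional path
(explicit N×N matrix) and a vectorized sliding-window path that collects
each window's ≤ 40 ordered pair codes and reduces them with sorted
run-length counting.  The test suite proves them equal per pixel and both
equal to a brute-force pair-enumeration oracle to 1e−12; the matrix builder
is also checked against `skimage.feature.graycomatrix` on a shared
configuration.

## Canopy height and volume

CHM = DSM − DTM with negative differences clamped to 0 (height is
physically non-negative; the clamp is switchable).  Volume is
Σ height × pixel area over the selected pixels that pass the mask — pixel
area comes from the georeference, never from a pixel-count heuristic.
Canopy overlap between adjacent vines is not corrected; it is an
acknowledged, irreducible source of per-vine volume error at 1.2 m spacing.

## Vine-row mask

Two routes, fused by intersection (union behind a flag) so that only
pixels both routes call canopy survive — the feature table must be
canopy-exclusive:

- **Pixel route** — strict `OSAVI > 0.7`, or an Otsu threshold on a
  256-bin histogram of the valid pixels.
- **Object route** — seeded region growing realized as a marker watershed:
  seeds at local maxima and minima of the index (labeled separately so
  flat scenes keep distinct markers), basins grown over the Sobel gradient
  magnitude with Moore-8 (default) or von-Neumann-4 connectivity.  Growing
  on the gradient rather than the inverted index keeps basins inside
  homogeneous areas and makes them meet at value edges, which is the
  similarity-driven behavior a region-growing segmenter is after.
  Adjacent segments whose means differ by at most `similarity_threshold`
  (default 0) are merged; segments of `generalization` (default 1) pixels
  or fewer are absorbed into the neighbor with the closest mean.  Segment
  means are then clustered by k-means (k = 6, deterministic k-means++ with
  fixed seed; cluster ids renumbered by ascending center so ties and runs
  are reproducible), and every cluster whose mean index exceeds the
  threshold is selected — at least the brightest one — replacing the
  manual cluster selection of a GUI workflow so the pipeline runs
  unattended (a manual cluster-id override remains).

The exact mechanics of GUI segmentation tools are *not* reproduced;
numeric agreement with any particular tool is a non-goal.

## Zonal aggregation

Each vine gets a 1.0 m (across-row) × 1.2 m (along-row) rectangle centered
on its stem, with the along-row axis parallel to the mean terrain aspect
(circular mean of the DTM's steepest-descent azimuths).  Pixel membership
is center-in with half-open edges (lower edges inclusive), so boundary
pixels belong to exactly one side.  Statistics use the population variance
convention.  The modeled feature per index/texture raster is the masked
rectangle *mean* (the seven full statistics are computed and retained);
texture features come from the red band by default (config-exposed), and
the CHM contributes mean, median, min, max, SD, variance and volume.
Median and min are stored but not part of the structural modeling group,
which is {CHM_mean, CHM_max, CHM_std, CHM_Volume}.  The seven feature
groups are the progressive unions: spectral (6), structural (4), texture
(4), sp+str (10), sp+tex (10), str+tex (8), all (14).  Vines whose
rectangle∩mask is empty keep CHM_Volume = 0 but have undefined spectral/
texture means; they are flagged `excluded`, logged, and dropped from
modeling — on default scenes this removes the canopy-free class-0 vines,
exactly as a canopy-exclusive mask should.

## Classification harness

Repeated k-fold (5 splits × 5 repeats, random state 1, plain k-fold by
default with a stratified option) produces 25 outer evaluations.  Within
each outer training portion a 3-fold grid search selects hyperparameters
by accuracy, then refits on the full portion — nesting avoids selection
leakage, and standard scaling lives inside the searched pipeline so it is
fit on training data only (a global-scaling variant would leak fold
statistics and is deliberately not the default).  Train/test accuracy and
support-weighted F1 are recorded per split; test predictions are pooled
across folds for confusion analysis.  The full published grids (SVM:
kernel × C × gamma; RFC: n_estimators × max_features × max_depth ×
max_leaf_nodes × max_samples × min_samples_leaf × criterion, with
`max_samples` read as absolute bootstrap counts as printed) are available;
the desk-scale default prunes them to the informative ranges (SVM:
C ∈ {0.1, 1, 10, 100}, gamma ∈ {0.01, 0.1, 1}; RFC: 100 trees,
depth ∈ {6, 15, 30}) so a full 7-group × 2-classifier run finishes in
minutes on one CPU.

One protocol note: the chance-level null check (permuted labels should
score 1/6 on six balanced classes) is run under *stratified* repeated
k-fold.  Plain k-fold is pessimistically biased under label permutation —
the class that happens to dominate a training fold is necessarily
underrepresented in the matching test fold — which depresses measured
accuracy by 2–5 points at n = 300 regardless of classifier.  Stratification
equalizes train/test class proportions and restores the textbook chance
level; this is a property of the evaluation protocol, not of the models.

## Evaluation

Confusion matrices are ordered by the ordinal class sequence
(0, 1, 3, 5, 7, 9), rows = labeled, columns = predicted.  User accuracy is
the row-normalized diagonal (correct / all vines carrying that label),
producer accuracy the column-normalized diagonal.  Neighbor-inclusive
match rates count the diagonal plus the ordinally adjacent classes; the
edge convention follows the reference survey's marking — the lowest class
also counts its second upward neighbor (0 matches 1 *and* 3), the highest
counts only its downward neighbor — with a strict ±1 variant available.
"Adjacent" is adjacency in the ordinal sequence, not numeric distance
(3 and 5 are neighbors).

Mann–Whitney U uses midrank ties; the two-sided p-value is exact (full
enumeration) when n₁+n₂ ≤ 12 and the pooled sample is tie-free, otherwise
a normal approximation with tie and continuity corrections (verified
within 0.02 of enumeration for all sample sizes up to 8 vs 8).  Two
identical samples yield U = n₁n₂/2 and p = 1 with a warning.  Significance
stars default to the conventional mapping (*** < 0.001, ** < 0.01,
* < 0.05); the mapping is overridable because published caption
conventions vary.  Per-vine prediction differences are ordinal rank
differences, true − predicted, so positive values mean the model
underestimated growth.

## Problem sizes

Desk-scale runs use 20×16 m to 40×30 m scenes (≈ 110–450 vines) at 0.05 m
pixels with the reduced grids; these sizes keep the full test suite and
the acceptance script within a few minutes on a single CPU while leaving
every class populated.  The volume-convergence check additionally runs at
0.025 m pixels.

## Known limitations

- Absolute classification accuracies on synthetic scenes are far higher
  than any field result; only qualitative orderings and recovery
  properties transfer.
- Per-vine masks are not split between adjacent vines; canopy overlap
  biases large-vine volumes slightly low.
- The OBIA stage is a documented equivalent of GUI region-growing tools,
  not a numerical reproduction of any of them.
- GeoTIFF support covers north-up, square-pixel, single-CRS rasters only;
  no reprojection.
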