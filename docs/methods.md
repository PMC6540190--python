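# Methods

## The problem this package models

Thermography is a screening tool for drought tolerance: water-stressed
plants close their stomata, transpiration cooling drops, and canopy
temperature rises. Screening genotypes therefore reduces to a chain of image
analysis and statistics — find the canopy pixels in a visible image, carry
that mask onto the thermal sensor's grid, read out leaf temperatures, and
compare the drought-induced temperature increase across genotypes with the
same factorial statistics used for conventional physiological traits.
`canopytherm` implements that chain end to end and supplies a synthetic
scene generator with exact ground truth so every stage is testable without
field data.

## Segmentation

The RGB image is converted to CIELAB (sRGB gamma decoding, linear RGB to
XYZ under D65, XYZ to L\*a\*b\*; no other illuminant is supported) and only
the chroma channels a\* (green–red) and b\* (blue–yellow) are used. Dropping
L\* makes the clustering insensitive to global lightness differences — the
suite asserts that shifting L\* by a constant leaves the labels unchanged.

Clustering is flat-kernel mean shift (scikit-learn's implementation) in the
2-D (a\*, b\*) plane:

* **Bandwidth.** Numeric, or `"auto"`: the 0.2 quantile of pairwise chroma
  distances on a seeded random subsample (default 1000 pixels). The
  quantile heuristic lands inside the within-population distance range, so
  modes stay well resolved. A bandwidth large enough to merge everything
  into one cluster is legal and merely logged.
* **Seeding.** Mode seeking runs on the subsample with bin seeding, and
  only bins holding at least `min_seed_fraction` (default 1%) of the fitted
  points may seed a search. Under a flat kernel, an isolated noise-tail
  pixel midway between the canopy and soil populations has no neighbours
  within the bandwidth, does not move, and would otherwise become its own
  "mode" that then captures mixed border pixels at assignment time.
* **Assignment.** Every pixel of the full image goes to its nearest
  converged mode; labels are renumbered contiguously ordered by ascending
  a\*, so greener clusters come first, and modes that own no pixel after
  full-image assignment are dropped.

Plant clusters are designated by a greenness rule — modes with a\* below a
threshold (default 0) are plant. The field workflow involved a human
annotator, so an explicit label override exists for manual designation. If
nothing qualifies, an empty mask is returned with a warning rather than an
error: an all-soil image is a legitimate observation.

The mask is finished with binary erosion by a square structuring element
(default 3×3, one iteration; both configurable) so that mixed
plant/background border pixels never enter the temperature statistics.
Out-of-frame pixels count as background, making erosion strictly
anti-extensive.

## Alignment

The visible and thermal sensors of a dual camera differ in resolution and
optical axis, so masks segmented in visible coordinates must be carried
into the thermal grid by a projective homography. The convention, binding
package-wide, is: 0-based (row, col) indices, origin top-left, homographies
acting on homogeneous (col, row, 1) triples, and H mapping visible →
thermal.

Estimation is least squares over annotated corresponding points via the
normalized direct linear transform: both point sets are centred and
isotropically scaled to mean distance √2, the 2N×9 design matrix is
assembled, the solution is the right singular vector of the smallest
singular value, then denormalized and scaled to H[2,2] = 1. Normalization
is essential for numerical conditioning; with it, noise-free recovery is
exact to ~1e−14 relative error. There is no RANSAC: the points are curated
human annotations, so plain least squares over all of them is appropriate,
and the per-point reprojection residuals are returned so bad annotations
are visible. Degenerate configurations are rejected twice — collinear
quadruples (or fully collinear larger sets) at construction, and a
collapsing nullspace (two near-zero singular values) at estimation.

Masks are warped by inverse mapping with nearest-neighbour sampling, which
keeps them strictly binary; pixels whose pre-image falls outside the source
domain become background. The nearest-neighbour quantization at mask
borders is why mask-consistency checks use a Jaccard ≥ 0.95 tolerance
rather than exact equality.

## Radiometry and canopy temperature

A thermal camera reports apparent temperature — the blackbody temperature
matching the observed radiance. A leaf is modelled as a greybody of
emissivity ε (default 0.98, the standard canopy value), so

σT_app⁴ = ε σT_obj⁴ + (1 − ε) σT_refl⁴,

with absolute temperatures, reflected background temperature T_refl, and
atmospheric transmission taken as 1 over the short ranges involved (full
atmospheric compensation belongs to camera software and is out of scope).
The correction inverts this closed form for T_obj; the forward model is
also exposed, and correct-then-forward round-trips to 1e−9. Imagery already
compensated in-camera bypasses the correction via a passthrough flag.

Canopy temperature (CT) is the arithmetic mean of masked pixel
temperatures. Outlying pixels are retained — the 5th/95th percentiles and
the median are always reported alongside so they stay auditable — and
histograms default to 0.5 °C bins spanning floor(min)…ceil(max). The
drought response is ΔCT = mean CT of stressed replicates minus the mean CT
of well-watered controls of the same genotype; the replicate-level table
(each drought CT minus the control mean) feeds the genotype comparison of
the increase itself.

Ground sampling distance is GSD = 2·h·tan(fov/2)/n_px; a 25° lens with 320
pixels across at 20 m gives 2.77 cm per pixel.

## Physiology

Pure formula operations with input validation: LRWC = 100(FW−DW)/(TW−DW);
Fv/Fm = (Fm−Fo)/Fm; gravimetric soil water content (wet−dry)/dry; daily
water consumption from pot-weight bookkeeping under daily refill (grams ≡
mL). Water-use efficiency is computed as A/E. Note the naming wrinkle: the
record schema labels this quantity iWUE although much of the literature
reserves "intrinsic" for A/gs; the A/E definition is kept deliberately and
the discrepancy documented here. A fresh weight slightly outside [DW, TW]
(a routine weighing anomaly) warns and returns the raw value rather than
failing; reported tables may cap LRWC at 100 while the raw value is
retained. Units are carried by the schema and never converted implicitly; a
validation pass flags impossible or implausible magnitudes.

## Statistics

Each response is analysed as a two-way fixed-effects ANOVA (treatment ×
genotype, completely randomized, ≥2 replicates per cell; fitted by OLS,
type-II sums of squares — identical to type I/III on the balanced designs
this targets). Assumption checks are *non-blocking*: Cochran's C for
variance homogeneity across cells and Shapiro–Wilk on residuals produce
warnings, not aborts, because partially heterogeneous responses are routine
in this kind of experiment and the factorial comparison is still the
analysis of record. Cochran's C has no installed implementation, so it is
computed directly (largest cell variance over the variance sum) with the
standard Bonferroni-through-F p-value bound; the test is sometimes
misnamed "Cochran's Q" in the agronomy literature — Q proper applies to
binary outcomes, and no response here is binary.

Mean comparisons are routed by the interaction:

* interaction p ≤ α → genotypes compared within each treatment;
* otherwise → treatments compared per genotype.

Pairwise comparisons use the studentized range (Tukey HSD; Tukey–Kramer SE
under unequal n) at the error degrees of freedom of the full two-way
model. The genotype comparison of ΔCT uses a one-way Tukey HSD on the
replicate-level increases.

Letters are assigned by insert-and-absorb: one column initially holds all
groups; each significant pair splits every column containing both; columns
absorbed into supersets are dropped; surviving columns become letters
ordered by their first group. The display satisfies the defining relation
exactly — two groups share a letter iff their adjusted p exceeds α — and
the suite checks this against a brute-force oracle for up to six groups.
Insert–absorb does not guarantee the globally minimal letter count in
pathological cases, but is minimal on the patterns these designs produce.

Pearson correlations come with the conventional interpretation bands:
|r| < 0.30 negligible, then low, moderate, high in 0.20-wide steps, and
0.90–1.00 very high, signed by direction. Boundary values belong to the
upper band (r = 0.30 is "low", r = 0.90 "very high"). Zero-variance pairs
are reported NA with a warning.

No multiple-testing correction is applied across responses and days are
analysed separately; mixed/repeated-measures models are out of scope.

## The synthetic generator

Scenes are deliberately minimal: plant canopies are unions of disjoint
disks of a green canopy colour over a warm soil background — sufficient
because every downstream operator is colour- or temperature-based, not
shape-based. The visible raster (default 640×480) and thermal raster
(default 320×240) use different grids linked by a known projective
homography (down-scaling plus a small shift, rotation and perspective
terms), so the alignment path is always genuinely exercised. The thermal
image is rendered analytically: each thermal pixel is classified by mapping
through the inverse homography into visible coordinates, so the
thermal-space truth mask is exact rather than resampled. Noise is i.i.d.
Gaussian, per channel in RGB (sd 8 by default) and per pixel in
temperature (sd 0.3 °C); object temperatures pass through the greybody
forward model at the scene emissivity. The generator's default emissivity
is 1.0, i.e. the written thermograms are camera-corrected apparent = object
temperatures, matching a workflow where compensation happens in-camera;
setting scene emissivity to 0.98 produces genuinely apparent imagery and
makes the pipeline's correction step load-bearing.

The experiment layer mirrors a four-genotype maize drought trial:
2 treatments × 4 genotypes × 5 replicate pots, completely randomized. Cell
means encode the canonical pattern — a common 28 °C control canopy,
drought increases of 5/3/1/1 °C (sensitive, intermediate, two tolerant
genotypes), collapsed gas exchange under drought (A 30→3 µmol m⁻² s⁻¹,
gs 0.25→0.02 mol m⁻² s⁻¹, E 5→0.8 mmol m⁻² s⁻¹), raised Ci, reduced leaf
and soil water, and genotype-dependent grain-yield losses (23/33/12/0 %).
Replicate noise is roughly 5–10 % of each mean (CT sd 0.3 °C). Derived
quantities (iWUE, Fv/Fm) are computed from the drawn values by the
physiology formulas, never drawn directly. One top-level seed feeds an
explicit per-unit sub-stream, so any single scene is reproducible alone and
whole fixture sets are byte-for-byte reproducible.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: leaf shape, self-shadowing and specularities, mixed
border pixels from optics rather than geometry, within-canopy temperature
gradients, lens distortion, annotation error in the corresponding points
(the generated correspondences are exact; noise studies add it explicitly),
or any energy-balance physics linking the physiological variables to the
temperatures (cell means are programmed, not mechanistically derived).

## Problem sizes and numerical choices

Tests and the acceptance script run on reduced rasters (visible 160×120,
thermal 80×60, canopy radius 25 px) with a mean-shift subsample of 400–500
and an explicit bandwidth of 12 chroma units where speed matters; the
canopy/soil separation is ~45–48 units, so the clustering is far from its
breakdown regime at either bandwidth choice. Monte-Carlo sizes: 100
experiment replications for the letter-pattern rate, 1000 null simulations
for the interaction false-positive rate, 500 replications for the Pearson
small-sample check.

Other numerics: homography degeneracy threshold at 1e−9 of the leading
singular value; homogeneous-coordinate w below 1e−12 (relative) treated as
the plane at infinity; percentiles by linear interpolation; histogram bins
right-open except the last; Tukey p-values from `scipy.stats.
studentized_range`; constant-residual vectors skip the Shapiro–Wilk test
(reported as p = 1). Scene-level results are independent of processing
order; all randomness descends from explicit seeds.

## Known limitations

* The greenness rule (a\* < 0) designates plant clusters; crops or soils
  with atypical chroma need the threshold moved or manual overrides.
* The greybody correction ignores atmospheric transmission; long-range
  imagery should be corrected upstream.
* Cochran's C p-values use the Bonferroni/F approximation with the average
  cell size under mild unbalance.
* The factorial machinery assumes a complete two-treatment × G-genotype
  layout; incomplete designs are rejected rather than approximated.
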