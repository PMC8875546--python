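# Methods

## Measurement model

All measurements operate on binary region masks rasterized from RGB
images with an isotropic calibration (µm per pixel). The coordinate
convention is 0-based, row-major, pixel centers at integer coordinates,
pixel-set semantics. Masks below 4 px are rejected as degenerate rather
than measured: shape metrics are meaningless below rasterization scale.

**Area** is the foreground pixel count times the calibrated pixel area.
For disks of radius 20–200 px this is within 1 % of πr² (Gauss-circle
bound).

**Perimeter** is the length of the sub-pixel 0.5 iso-contour polygon of
the mask after Gaussian pre-smoothing with σ = 1 px. The smoothing is
load-bearing: the raw marching-squares contour of a binary mask is a
mid-crack polygon that overestimates a disk circumference by ≈ 5 %,
while the smoothed level set moves a convex boundary by only
σ²/(2R) ≈ 0.02 px at R = 20 px. Measured bias on disks r = 20–200 px is
below 0.6 %; an axis-aligned square reads ≈ 396.6 for a true 400 (corner
rounding), within the 2 % envelope we consider faithful to manual vector
tracing. Only the outer contour is measured; holes are ignored.

**Perpendicular diameters** interpret "the two longest perpendicular
diameters" as the maximum Feret (caliper) diameter over the convex hull
of pixel centers, plus the maximum caliper extent measured perpendicular
to that direction. Ties in the Feret direction break toward the smallest
angle in [0, π). This is orientation-independent and reproducible,
unlike a horizontal/vertical convention; rotating an 80/40 ellipse by
30° changes either diameter by < 2 %. Whether a human would place the
calipers through the centroid is not specified anywhere we could anchor
it; the convex-hull caliper is declared as this package's convention.

**Epithelium thickness** casts five rays from the lumen centroid at
seeded uniform-random angles; each length is the distance between the
ray's lumen-boundary exit and its tubule-outer-boundary exit, and the
reported thickness is their arithmetic mean. Rays are marched at 0.1 px
steps with nearest-neighbour mask lookup, giving crossings accurate to
about half a pixel. A ray that fails to cross both boundaries (possible
for strongly non-convex lumina) is resampled, with a bounded retry
budget. For strongly non-convex lumina the first outward crossing pair
is used.

## Derived quantities

The per-tubule quantities are pure arithmetic on the measurements:
epithelium area = tubule − lumen area, epithelium area ratio, average
diameters; the section-level quantities are the tubule count, the
Bergmann–Kliesch percentage (positive / total × 100), interstitial area
(section − Σ tubule areas, all tubules including longitudinal ones),
tubule area ratio and tubule number density. Percentages are computed as
`100 * (num / den)` — ratio first — so they can never exceed 100 by a
rounding ulp. Detailed per-tubule measurement (areas, diameters,
thickness) excludes longitudinally sectioned tubules; counting and the
area sums include them. Edge-touching tubules do not occur in phantoms;
on external masks they are kept for counting and area sums.

Sampling of tubules for detailed measurement is a seeded uniform draw
without replacement from the cross-sectioned tubules only, default
target 100 (the upper end of common practice, configurable); when fewer
exist, all are taken and a warning logged.

## Phantom generator

The phantom emulates one testis cross-section: a slightly elliptical
section (axes R and 0.92 R) packed with non-overlapping elliptical
tubules, each with a concentric lumen scaled by `lumen_fraction` and
annular epithelium between. Packing is seeded rejection sampling on
circumscribed circles with a 2 px minimum gap and a 2 px section margin,
placing the largest tubules first; exhausting the attempt budget (5000
per tubule) raises a packing-infeasible error.

Tubule shape families are disjoint by construction: cross-sections have
axis ratio ≤ 1.3, longitudinal profiles ≥ 2.5, so the segmentation
aspect cutoff of 1.8 sits in a dead zone and plane classification on
phantoms is unambiguous. Exactly `round(n · longitudinal_fraction)`
tubules are longitudinal and exactly
`round(n · spermatid_positive_fraction)` of the cross-sections are
spermatid-positive. Positive tubules carry six dark speckles (6 px long,
2 px wide, aspect ≥ 3) just inside the lumen boundary — the detection
substrate for the marker detector. Speckles occupy evenly spaced angular
slots with bounded jitter so they can never merge into fewer blobs than
planted.

Defaults (section radius 1200 µm, 30 tubules of 90 ± 10 µm radius,
lumen fraction 0.55, 10 % longitudinal, 60 % spermatid-positive, 2 µm/px)
describe a rat-scale section at desk resolution with well-separated
tubules. No published quantitative distribution of rat tubule morphology
is encoded; these are explicit, configurable conventions, not
literature-derived parameters.

The H&E renderer uses a flat five-colour palette (white background, pale
pink interstitium, dark purple epithelium, pale lumen, near-black
speckles). It deliberately contains no texture, nuclei, staining
gradients, or noise. Consequently the segmentation results on phantoms
are essentially exact (IoU ≈ 1), and passing phantom tests demonstrates
the correctness of the measurement chain — not robustness of the
thresholds on real histology, which would require annotated slides and
is out of scope.

The IHC renderer is the exact Beer–Lambert forward model of the
deconvolution branch: per pixel `RGB = round(255 · 10^(−M c))`
(half-to-even, clipped to [0, 255]) with counterstain OD applied
everywhere in tissue and DAB OD on the positive structures (the
epithelium of spermatid-positive tubules, or — for coverage-controlled
experiments — exactly `round(coverage · tissue pixels)` pixels).
Ground-truth concentration fields are returned losslessly.

## Segmentation

Operators assume phantom-like contrast and are parameterized in
`SegmentationParams`: the section is the largest connected non-white
component with holes filled; tubules are dark (luma < 0.75) ring
components, hole-filled, split by a distance-transform watershed seeded
at their pale interior lumina when a component contains more than one,
and filtered at 500 µm² minimum area; lumina are the pale interior
regions (speckle holes re-filled). Plane classification thresholds the
best-fit-ellipse axis ratio at 1.8. The spermatid detector counts dark
(luma < 0.30) blobs with eccentricity ≥ 0.9 and major axis ≥ 3 px inside
the lumen dilated by 10 % of the tubule's equivalent radius, declaring a
tubule positive at ≥ 3 blobs. All parameters are conventions validated
against phantoms only.

## IHC quantification

Colour deconvolution follows the standard unit-stain-vector linear
model: per channel `OD = −log10(max(I, 1)/255)` (the clip at 1 bounds
OD on saturated pixels), concentrations are the stain-matrix inverse
applied per pixel, negative concentrations clipped to zero with the
clipped fraction logged. The default H-DAB matrix uses the published
hematoxylin (0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776) vectors,
normalized, with the residual as their normalized cross product;
alternative matrices can be supplied.

The per-stain 8-bit encoding `I = round(255·10^(−c))` makes the optical
density formula `log10(255/mean)` the exact inverse of the encoding on
uniform fields. Round-trip error through 8-bit quantization stays below
0.02 OD for stain concentrations up to 2 (beyond that, combined optical
densities push channels below intensity 1, which 8 bits cannot
represent).

Thresholds are dark-pass (`value ≤ T`). The default is Otsu computed on
the ROI-restricted histogram, with a manual override; a constant channel
makes Otsu undefined and raises an error suggesting a manual threshold —
this occurs by design on phantom counterstain channels, which are
uniform, so the pipeline's counterstain cut defaults to a loose manual
threshold (240) that selects the entire stained area, matching its
semantic role as the denominator. The mean pixel value for the OD is
computed over threshold-selected pixels only, and cleared-background
(white) pixels can never pass a dark-pass threshold, so ROI exclusion is
structural. The positively-stained area percentage requires a
counterstain denominator; on counterstain-free stains (mean counterstain
OD < 0.02 over the ROI) the package reports OD only and refuses the
percentage with an explanatory note rather than guessing a denominator.

## Determinism and reporting

Every random choice (packing, speckle placement, thickness rays,
sampling) flows from explicit integer seeds; per-tubule thickness seeds
are derived from the run seed and the tubule label so records do not
depend on processing order. CSV reports render floats at 6 significant
digits, and identical configurations produce byte-identical files. The
validation suite and the acceptance script use the default phantom
(30 tubules, ≈ 1.2 k × 1.2 k px) and a handful of smaller scenes; these
sizes keep a full run under a minute while leaving every oracle
comfortably inside its tolerance.

## Known limitations

- Segmentation parameters are tuned to the phantom palette; real H&E
  slides (texture, touching tubules, stain variation) will require
  retuning or learned models, which are out of scope.
- The thickness estimator assumes the lumen centroid lies inside the
  lumen; extremely crescent-shaped lumina would need a medial-axis
  formulation.
- Optical density is uncalibrated by construction (no step-wedge
  calibration), suitable for relative comparisons only.
- Anisotropic calibration and 3-D measurements are unsupported.
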