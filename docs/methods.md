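# Methods

This note records the models, conventions and numerical choices behind
`seedvision`, and what the synthetic benchmark does and does not establish.

## Segmentation

Frames are `(H, W, 3)` uint8 RGB with seeds brighter than the background
(a polarity flag inverts this).  The gray image is the channel mean
`(R+G+B)/3`.  The default threshold is Otsu's method; a fixed integer
threshold is available for exact reproducibility.  The binary image is
cleaned by a morphological opening with a disk structuring element
(default radius 2 px; one erosion then one dilation, with the erosion
border treated as foreground so a solid field passes unchanged), then holes
— background regions not 4-connected to the border — are filled.
Foreground components are 8-connected; components below `min_area`
(default 50 px, a dust filter) are dropped.  Regions are reported row-major
by centroid with 0-based `(row, col)` coordinates and half-open bounding
boxes.  Boundary contours are traced by clockwise Moore boundary following
with Jacob's stopping criterion.

A degenerate constant frame under Otsu yields an all-false mask and a
warning rather than an error, since sorter lines occasionally deliver empty
frames.

## Shape descriptors and discretization conventions

All 15 descriptors are functions of a small geometric summary.  Rasterized
shapes do not have unique perimeters or diameters, so the conventions were
chosen so that measured values of rasterized primitives track the
continuous formulas within about 1–2 %:

* **Area** `A` is the pixel count.
* **Perimeter** `P` is the length of the marching-squares sub-pixel outline
  after resampling to uniform 0.5 px arclength and smoothing with a
  wrapped Gaussian (σ = 0.8 px).  A raw 8-connected chain perimeter
  overestimates a disk's circumference by ~5 %, which would push the
  circularity of a perfect disk to ≈ 0.9; the sub-pixel smoothing removes
  the quantization staircase while shortening an axis-aligned rectangle's
  outline by under 1 %.  The resampling starts at the outline vertex
  farthest from the centroid — an intrinsic point — so congruent shapes
  measure identically.
* **Feret extents** `Dmax`/`Dmin` are measured on the convex hull of the
  boundary-pixel corner points (each pixel a unit square).  `Dmin` is the
  minimum caliper width over 1° rotations (ties: first angle).  Corner
  points make a `w × h` rectangle measure exactly `√(w²+h²)` and `min(w,h)`.
* **Circumcircle** is the minimum enclosing circle (Welzl's algorithm on a
  deterministically shuffled point list) of the pixel-center boundary
  contour, so a rasterized disk's defect ratio is ≈ 0 rather than the
  half-pixel-band artifact a corner-based circle would give.
* **Moment ellipse**: semiaxes `a ≥ b` from the second central moments with
  the per-pixel `1/12` variance term, making a discrete rectangle's moments
  equal its continuous values exactly.
* **Quadrant areas** `A1..A4` are pixel counts in the four quadrants cut by
  the principal axes through the centroid, numbered counterclockwise from
  the (+major, +minor) quadrant.  Pixels within 10⁻⁶ px of an axis are
  split evenly between adjacent quadrants, so `A1+A2+A3+A4 = A` exactly.
  The positive direction of each axis is canonicalized by the sign of the
  third central moment along it, making the numbering intrinsic to the
  shape; without this, 90° rotations would relabel quadrants and change the
  symmetry area ratios `|1 − (Ai+Aj)/(Ak+Al)|` of asymmetric shapes.

Out-of-roundness, the convex-hull interior-angle extremes, and the deepest
convexity defect have no standard closed forms; they are implemented as
documented substitutes: `(Rmax − Rmin)/Rmean` over centroid-to-contour
radii; min/max interior angle of the contour-corner hull polygon; and the
maximum distance from the contour to its own convex hull.  The hull-angle
and convexity-defect features are measured on the raster boundary: they are
exactly invariant under 90° rotations and mirror flips but **not** stable
under re-rasterization (arbitrary rotation or rescaling), which the
property tests scope accordingly.  `max_convex_distance` is in pixels and
is therefore not scale-free.

Preconditions: regions need at least 5 px; collinear (1-px-line) regions
are rejected, as are zero denominators (the error names the feature).

## Color

The geometric HSI model is used: `I = (R+G+B)/3`,
`S = 1 − 3·min(R,G,B)/(R+G+B)` (0 for black), and hue from the arccos
formula, reflected to `360° − θ` when `B > G`, with hue defined as 0 for
achromatic pixels.  Means are taken over mask-true pixels only.  Hue is
reported as degrees/360 and averaged arithmetically by default — adequate
for the brown/gray seed palette, but biased for hue distributions
straddling 0°/360°; a circular mean is available (`circular_hue=True`).
The gray mean equals the HSI intensity mean under this model, so one
feature serves as both.

## Texture

GLCMs are asymmetric pair counts at displacement `d` (default 1 px) along
0°, 45°, 90°, 135°, restricted to pairs whose both pixels are mask-true,
normalized to sum 1.  Gray values are quantized into 16 equal-width bins
over [0, 255] (configurable).  Statistics: `ASM = Σp²`,
`ENT = −Σ p ln p` (natural log; the conventional negative sign is applied
so entropy is nonnegative), `CON = Σ(i−j)²p`, `HOM = Σ p/(1+(i−j)²)`.
Per-orientation values are combined by the arithmetic mean, making the
aggregated statistics exactly invariant under 90° image rotations.

The local similarity pattern (LSP) is defined here as a rotation-invariant
8-neighbour operator: for each interior mask pixel, the fraction of
neighbours whose absolute gray difference from the center is at most
`similarity_t` (default 10 gray levels).  Its mask-wide mean drops in the
presence of spots and local defects.  Coarseness is Tamura-style: per
pixel, window averages at sizes 2^k (k = 1..kmax, default 4) are compared
through directional average differences, the best window size is kept, and
the mask-wide mean of best sizes is reported.  `kmax` shrinks automatically
until the window fits the region; a region smaller than the smallest
window is an error.  Windows near the mask boundary include background
pixels — acceptable for compact seeds, a known bias for very thin regions.

## Networks

Three layers, logistic sigmoid in hidden and output layers, one-hot
targets `(good, ng)` with MSE loss.  The hidden size follows
`nh = ⌈0.5·(ni + no)⌉`; the ceiling is forced by the 9-input color–texture
configuration, which uses six hidden nodes.  Inputs are min–max scaled to
[0, 1] with bounds fitted on training data (validation values clip;
constant features are rejected by name).  Training is online gradient
descent: weights start uniform in [−0.5, 0.5], samples are visited in a
freshly shuffled order each epoch, and updates follow every sample at
learning rate 0.01.  Training stops when the epoch-mean MSE falls below
0.01 (defaults; both configurable) or after `max_epochs` (default 10,000),
in which case the model is flagged non-converged but returned.  All
randomness derives from one seed, so training is bit-reproducible; the
inner loop is numba-compiled with a pure-NumPy fallback implementing the
same arithmetic.  Prediction takes the argmax of the two outputs; an exact
tie is graded NG (the conservative choice for a sorter).  The final grade
is the AND of the two networks' verdicts.

## SFFS

The search starts from a designated basic feature, alternates a forward
step (add the candidate with the highest criterion; ties toward the lowest
feature number) with conditional backward steps (remove a feature while
the reduced subset strictly beats the best score previously seen at that
size).  Forward steps are accepted even when they lower the score — the
non-monotone trajectories are the point of the floating variant — so the
search runs until the pool is exhausted or the step budget (default 30) is
reached, and the best subset is the trace-wide argmax.  The criterion is a
single seeded train/validation split accuracy, not cross-validation, which
keeps each evaluation cheap and deterministic.  SFFS is a heuristic: it
equals exhaustive search on the crafted oracle instances in the test
fixtures, not in general.

## Evaluation

The confusion matrix is rows = predicted, columns = actual, classes
(good, NG).  Per-class accuracies are column-normalized diagonal entries;
the overall accuracy is pooled (total correct / total), which for unequal
class sizes is the weighted — not unweighted — mean of the per-class
accuracies.  Percentages are rounded to 2 decimals.

## Synthetic frames

The generator emulates a detection-region snapshot: a grid (default 3×7 =
21 seeds per frame, default 400×400 px — a desk-scale stand-in for full
1600×1200 frames) of anti-aliased seed blobs (3×3 supersampled coverage)
on a noisy dark field (gray 10, σ 1).  Shape classes: circle; 1.25:0.8
ellipse (oval); 1.7:0.55 ellipse (elongated); three-lobed radial profile
(triangular); random low-order radial harmonics (irregular).  Surface
colors (RGB): reddish-brown (165, 85, 50), black (100, 90, 80), gray
(150, 150, 148), white (215, 212, 205), each with per-seed jitter, a
radial shading gradient, additive Gaussian roughness (σ 2–4 for sound
surfaces, 5–8 for defective ones) and Poisson-placed dark spots (density
up to 0.015 spots/px for sound seeds, 0.04–0.10 for defective ones; spot
gray is floored at 70 so spots read as surface defects, not holes).

The ground-truth grade is the generator's own rule, mirroring the
phenotypes the classifier is meant to separate:

    good  ⇔  shape ∈ {circular, oval}
             and color ∈ {reddish_brown, black}
             and spot_density < 0.02

NG seeds violate one aspect chosen uniformly, plus each remaining aspect
independently with probability 1/4.  Per-aspect truth columns
(`shape_ok`, `colortex_ok`) let each network be trained on the aspect it
can actually see, mirroring the separate per-net datasets such sorters are
trained with; the end-to-end benchmark is still scored against the overall
AND-rule label.

What the generator does **not** emulate: specular highlights, shadows and
seed-to-seed illumination gradients; partial occlusion and touching seeds;
the hidden side of the seed (a camera sees one face); defocus; and real
biological within-class variation beyond the parametrized jitters.
Passing the synthetic benchmark therefore demonstrates that the pipeline's
machinery is correct and well calibrated, not that the accuracy figures
transfer to real seed imagery.

## Problem sizes and benchmark conditions

The end-to-end benchmark trains on 300 rendered seeds (150 good / 150 NG;
half for SFFS training, half for validation; subset evaluations capped at
400 epochs, final networks at 3,000) and tests on 400 fresh seeds in 20
frames of 20, all seeds fixed.  Under these conditions the dual-network
AND rule grades ≈ 99–100 % of test seeds correctly, comfortably above the
90 % bar the suite asserts.

## Known limitations

* Hue averaging is arithmetic by default (see Color).
* GLCM/LSP windows near the mask boundary mix in background pixels.
* Hull-angle and convexity-defect features are raster-sensitive.
* The sorter-hardware side (feeding, suction, valve timing) is out of
  scope; this package is the vision and classification software only.
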