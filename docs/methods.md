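# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `radshape`.  It is written for a reader who wants to judge
what the package's results do and do not demonstrate.

## Synthetic bone model

A specimen is a solid whose cross-section at axial position `z` (the main
axis, +z distal) is a superellipse

    |(x − c(z)) / a(z)|^p + |y / b(z)|^p = 1 ,

with half-width `a`, half-depth `b` and squareness exponent `p`
interpolated monotonically (PCHIP) through a small set of axial stations,
and `c(z) = κ z (L − z)` a gentle lateral bow of curvature parameter `κ`.
Two Gaussian prominences complete the anatomy the pipeline consumes:

* a **dorsal tubercle** — a displacement along +y with angular width
  σ_θ = 0.45 rad and axial width σ_z = 1.2 mm, centred at `z_t`
  (default 8.5 mm proximal of the shaft end), prominence ≈ 2 mm;
* a **styloid process** — an axial (+z) displacement of the distal dome,
  a Gaussian of σ = 3 mm in the cross-section plane centred at 55% of the
  lateral half-width, height 3 mm, fading proximally below the shaft end.

Shaft ends are closed by superellipsoidal domes, giving a watertight,
consistently oriented surface grid.  Left bones are exact mirror images
(x → −x) of right bones with identical parameters.  Because the solid is
defined per-z, every cross-section perpendicular to the axis is known in
closed form (`analytic_section`), so pipeline measurements on the mesh have
an analytic oracle; on a circular-profile cylinder the mesh measurements
agree with the closed form to <1% at 0.5 mm edges.

Ground-truth landmarks (the continuous surface's distal apex and most
dorsal tubercle point) are computed from the parametrization on a dense
grid, independent of mesh resolution.

### Calibration

The default female parameters are solved, not tuned: the distal-plane
anchors (width 29.0 mm, depth 21.0 mm, area 472.6 mm²) fix `a`, `b` and
`p` at the tubercle station — the depth anchor accounts for the tubercle
bump (`2b + prominence = depth`), and the squareness exponent is found by
bisection so the analytic contour area (bump included) matches the area
anchor.  The middle/proximal anchors (28.2/19.5/427.5 and 26.3/17.2/353.2)
fix the taper at the axial positions where the pipeline will construct
those planes, i.e. at `z_t − d/4` and `z_t − d/2` with `d` the
styloid–tubercle axial gap computed per specimen from the cap/styloid
geometry.  With the default gap (~14.5 mm) the planes come out ~3.6 mm
apart, in the range reported for adult distal radii (3.5 ± 0.6 mm).
Perimeter is *not* calibrated; a superellipse with the anchored
width/depth/area has a perimeter of ≈79 mm at the distal plane, below
the ≈86 mm reported in vivo — the convexified synthetic section lacks the
concave dorsal grooves of a real radius.

### Population model

`PopulationConfig` draws, per specimen, five latent factors:

| factor      | default SD | effect |
|-------------|-----------|--------|
| scale       | 2.1/29.0 (relative) | isotropic size, from the female distal-width variation |
| taper       | 0.15 (relative)     | modulates the distal→proximal shrink around its calibrated value |
| tubercle    | 0.3 mm              | prominence, recalibrated so distal depth is preserved |
| curvature   | 3e-4 /mm            | axial bow |
| squareness  | 0.05 (relative)     | section roundness/boxiness |

Gender is an isotropic size factor of 33/29 (the reported male/female
distal-width ratio); size, not shape, dominates the reported gender
differences, so no gender shape effect is planted.  Side affects the mean
shape only by mirroring; `side_variance_ratio` scales the left-side latent
SDs to emulate the reported higher left-side shape variance (default 1.0 —
no side difference — matching the reported absence of side differences in
size).  Vertex positions receive 0.03 mm Gaussian noise along normals
(segmentation jitter).  All draws come from one seeded generator; a seed
reproduces the population byte-for-byte.

What the generator does *not* emulate: articular surface geometry, the
concave dorsal/volar grooves (hence the perimeter shortfall), cortical
thickness or interior structure, age effects, and non-size gender shape
differences.  Passing tests therefore demonstrate the pipeline's
correctness and calibration on a smooth, convex-sectioned bone family —
not segmentation robustness on clinical CT surfaces.

## Mesh processing

Coordinates are always millimetres in a right-handed frame; voxel masks are
0-based with the world origin at the centre of voxel (0,0,0).  The default
working edge length is 0.5–1.5 mm depending on stage; resolution is a
configuration knob and every reported number states the resolution used.
Refinement subdivides longest edges (geometry unchanged); coarsening
re-extracts a marching-cubes isosurface of the signed-distance field
sampled at 1.15× the target edge (the grid origin is offset by 0.1379 of
the pitch to keep nodes off the exact surface, which would create
degenerate triangles).  Mask-to-surface conversion Gaussian-smooths the
binary mask (σ = 1 voxel) before isosurfacing, which removes voxel
staircase area bias; objects too thin to survive smoothing fall back to
the exact voxel-boundary surface.

Because the environment provides no R-tree bindings, closest-point queries
use an in-package vectorized point-to-triangle projection with a
k-nearest-centroid candidate search (k = 16); the signed-distance sign
comes from the nearest triangle's face normal, adequate for clean
watertight surfaces.

## Alignment

Rigid registration is ICP with Kabsch (SVD) updates.  Correspondences for
mesh targets are the closest points on the *surface*; nearest-vertex
matching was evaluated and rejected because it stalls on discretization
plateaus (about 4° rotation error on a 10° test case) and cannot meet the
recovery tolerances (<0.01°, <1e-3 mm) that surface projection achieves
(~1e-9).  Coarse initialization aligns centroids and principal axes, with
180° ambiguities resolved by third-moment skew along the long axis (the
styloid is distal) and the short cross-section axis (the tubercle is
dorsal); the remaining axis completes a right-handed frame, so mirror-image
specimens are not spun half a turn.

Generalized Procrustes alignment iterates optimal superposition to the
evolving mean until the mean moves <1e-9.  **Scaling is off by default**:
the downstream morphometrics and gender classification are size-bearing,
and removing scale would delete that signal.  A similarity mode
(`allow_scaling=True`) exists; it pins the gauge by holding the mean's
centroid size constant.

Left specimens are *not* mirrored before alignment: side-specific shape
information is retained deliberately, which is what makes side
classifiable at all.  A rigid transform cannot map a left bone onto a
right reference, so cross-side template projections legitimately reach
roughly twice the styloid's lateral offset; the pipeline therefore sets
the correspondence guard to 30% of the reference bounding-box diagonal,
while the single-specimen default stays at 10 mm (a gross-misregistration
tripwire).

## Correspondence

Dense correspondence is template projection: the reference specimen's
vertices are subsampled to `n` landmarks (default 2000) by seeded
farthest-point sampling, and landmark *i* of every specimen is the closest
point on that specimen's registered surface.  This replaces
optimization-based correspondence (e.g. minimum-description-length):
projection is exact on this synthetic family, where specimens are smooth
near-identity deformations of the template, and the interface
(`CorrespondedShape` in, `CorrespondedShape` out) admits a drop-in
optimizing replacement.  On strongly creased or high-curvature real
anatomy, projection can slide correspondences across features — a known
limitation.

## Shape model

PCA via SVD of the centered `N × 3n` data matrix (covariance divisor
`N − 1`), rank-limited to `N − 1`; eigenvalues below a scale-aware floor
(~1e-20 of the squared data magnitude) are flushed to exact zero so that a
population of identical shapes reports zero modes.  Mode signs are fixed by
making each mode's largest-magnitude entry positive.  The mode count uses
the inclusive rule: eigenvalues [19, 1] reach the 0.95 threshold with one
mode.  Five models are built per run: overall, per gender and per side.

## Cut planes and morphometrics

Landmark detection operates on the registered mesh: the styloid tip is the
vertex of maximal +z, the tubercle point the vertex of maximal +y within
the distal 25% of the axial extent (the window prevents the dorsal shaft
bow from hijacking "most dorsal").  A feature is accepted only if every
vertex within 0.6 median edge lengths of the maximum stays within 35% of
the cross-sectional extent of the maximizer — a flat cap or a straight
dorsal line (e.g. a plain cylinder) fails with "landmarks not
identifiable".

Plane offsets are measured **along the main axis** (projected), not as
Euclidean landmark distances, because the planes are defined by axial
positions.  Width and depth are axis-aligned extents in the standardized
frame (medio-lateral and dorso-volar), not rotating-caliper Feret
diameters: the frame is standardized before cutting, and maximum width in
the radiological sense is the medio-lateral extent.  Mesh–plane
intersection segments are chained into closed loops (an open chain, i.e. a
non-watertight mesh, is an error naming the gap); when a cut produces
several loops — possible near the styloid — the largest-area loop (the
shaft) is measured.  Area is the shoelace formula; perimeter the polygon
edge sum.

## Statistics and classification

Normality: Lilliefors-corrected KS test (plain KS against fitted
parameters is anti-conservative).  Group comparisons: pooled-variance
Student t (Welch available), significance at the exact 0.05/4 = 0.0125
(printed as 0.013).  Across-plane comparison: one-way ANOVA with Bonferroni
post hoc (raw p × 3, capped at 1).

Classification repeats the complete LOOCV sweep 100 times with fresh
forest randomness — LOOCV itself has no sampling freedom, so repetition
with different forest seeds is the only reading under which a *median*
classification probability over iterations is meaningful.  The median
over iterations of the per-sweep accuracy fraction is the headline number;
the mean predicted probability of the true class is exposed as a secondary
output.  Forests use 50 trees, unlimited depth, √p features per split,
bootstrap on.  The step-wise scheme trains the gender forest only on
specimens of the predicted side and counts success only when both labels
are right.  Features default to shape-model coefficients; cut-plane
morphometrics are a switch.

## Problem sizes and numerical choices

The shared end-to-end test run uses 40 specimens at 1.5 mm edges with 300
landmarks; the calibration round-trip samples 500 female specimens — at
0.8 mm edges through the full mesh pipeline in the acceptance script, and
via the analytic sections in the test suite.  These sizes were chosen as
the smallest at which the planted effects are unambiguous (gender t-tests
at p ≤ 1e-3, Monte-Carlo error on plane means ≈ 0.3%).  ICP subsamples
4000 source points by default (2000 in the pipeline) and stops when the
RMS improves by <1e-10; GPA stops at mean shift <1e-9; calibration
bisection solves the squareness exponent to 1e-10.

## Known limitations

* Template projection is not an optimizing correspondence; population
  statistics on real, strongly featured anatomy would inherit its sliding
  bias.
* The signed-distance sign (face normal of nearest triangle) can
  misclassify points near sharp concave creases; irrelevant for the smooth
  synthetic family, relevant for remeshing arbitrary CAD-like geometry.
* Classification accuracies on small synthetic populations are not
  comparable to values reported for clinical cohorts; only the procedure
  and its behaviour on planted structure are validated.
* The perimeter of the synthetic sections is systematically below in-vivo
  values (convex section family); width, depth and area are calibrated,
  perimeter is emergent.
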