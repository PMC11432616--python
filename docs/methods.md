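# Methods

This note documents the models behind `aortamorph`, the parameters that
matter, the numerical choices, and what the phantom-based validation does
and does not establish.

## Problem setting

After thoracic endovascular aortic repair, the stiff stented segment
redistributes deformation to the un-stented ascending aorta and the heart.
The package quantifies that remodelling from segmented 3-D anatomy using
purely geometric measurements: the aorto-septal angle (AoSA) between the
left-ventricular and aortic axes, the inclination of the first 2 cm of the
ascending aorta, and per-segment centerline metrics including the lengths
of the outer and inner wall curvature lines. The inputs are a triangulated
aortic wall (open tube, side branches removed upstream) and a chamber
segmentation; no image processing beyond marching cubes is performed here.

## Geometry

### Surfaces and label volumes

All geometry lives in world millimetres; label volumes carry a 4×4
voxel-index→world affine (0-based indices), and mesh files are assumed
already in world mm. On ingestion, duplicate vertices are merged at
1e-6 mm, degenerate faces dropped, edge-manifoldness enforced, and boundary
loops traced with the orientation induced by the adjacent face winding.
Surfaces extracted from labels use marching cubes at level 0.5 of the
binary mask followed by Taubin smoothing (λ = 0.5, μ = −0.53, 10
iterations by default) — a volume-preserving smoother; on a 20 mm voxel
ball the enclosed volume changes by < 0.1% and the area error is ~1%.
The separating surface between two labels (e.g. ventricle/atrium, where
the mitral valve lies) is triangulated from the 6-connected shared voxel
faces; its anchor point is the area-weighted mean of the triangle
centroids. A `clip_with_plane` utility opens capped vessels (e.g. from
voxelisation) so the solver sees inlet/outlet rings, peeling faces at
pinched boundary vertices until the rim is manifold.

### Harmonic parameterisation

The vessel wall is parameterised by the solution of the Laplace equation
with Dirichlet data 1 on the inlet ring and 0 on the outlet ring,
discretised with the cotangent-weight (linear FEM) Laplacian and solved
directly (sparse LU). The cotangent weights are intrinsic, so isoline
geometry converges under refinement instead of following triangulation
density; on a developable straight tube the linear-in-height solution is
reproduced to machine precision at any resolution. Isolines are taken at
the `n_levels` equidistant levels `k/(n_levels+1)` (default `n_levels` =
100, giving sub-millimetre spacing on aortic lengths); each contour is
chained face-by-face from edge interpolations into a closed polyline.
Levels colliding with a vertex value are perturbed by 1e-12 for a
deterministic tie-break; if a level produces several closed components
(can happen on aneurysmal bulges) the longest is kept and a warning
logged.

### Centerline

The raw centerline is the sweep of isoline centroids (arc-length-weighted
polyline centroids, robust to uneven contour sampling) from the inlet ring
centroid to the outlet ring centroid. It is smoothed with a
Savitzky–Golay local quadratic over a `smooth_window` = 10 mm arc-length
window and resampled at `resample_step` = 0.5 mm. A local quadratic was
chosen over a plain moving average deliberately: an averaging window
contracts a circular arc of radius R by O((w/2R)²) — ~0.26% of length at
w = 10 mm on R = 40 mm — which is amplified into a several-percent
tortuosity bias because `T = L/D − 1` divides by the small excess `L − D`.
The quadratic fit preserves curvature to second order; the residual length
bias on the quarter-bend phantom is +0.18%. Savitzky–Golay kernels have
negative side lobes, so smoothing may *slightly lengthen* an already
smooth curve (it is not a contraction); what it guarantees instead is
noise suppression, which is what the tests assert. Arc length is measured
*along* the smoothed polyline (the resampling parameter), which is exact
for the uniform-spacing contract and a better length estimate than
re-chording the resampled points.

Cross-sections intersect the wall with the plane orthogonal to the local
tangent (central differences); among the closed intersection loops the one
enclosing the centerline point (planar winding test) is kept, and its area
is the planar polygon area. Sections that fail to close (typically the
extreme ends) are recorded as missing rather than guessed. The equivalent
diameter is `2√(A/π)` — i.e. sections are treated as circles, which for
diameter reporting matches the field's convention.

### Curvature lines

Each isoline (plus the inlet/outlet rings as first and last layers) is
resampled to `samples_per_contour` = 64 equally spaced nodes, loops are
oriented consistently (Newell normal against the travel direction), and
consecutive layers are phase-aligned by minimising the summed squared
distance over a *continuous* fractional offset (coarse whole-sample scan,
then a bounded scalar refinement). Sub-sample alignment matters: a
whole-sample-only alignment leaves a rounding residual of a fraction of a
sample per layer that accumulates into a systematic twist over ~100 layers
and destroys the inner-line estimate. The outer (inner) curvature line is
the corresponding-node polyline of maximal (minimal) total length, ties
broken by smallest angular index. On bend phantoms the recovered lengths
match `(R ± r)·θ` to < 0.1%, and doubling the sampling to 128 changes them
by < 0.06%.

A note on the path model: a layered-graph formulation that connects all
node pairs of consecutive contours and takes the *maximum*-cost path does
not measure wall curvature — the maximal path zigzags across the lumen and
its length grows with the number of layers (≈ 2000 mm on a 78 mm phantom).
The correspondence construction keeps both extremal paths on the wall,
which is what "the points that create the longest and shortest paths,
connected in order" means geometrically. Paths use straight chords between
consecutive contour points; no geodesic refinement on the surface is
attempted. The extremal-generator model is exact for planar tubes whose
bends all curve the same way (the ascending-aorta use case); for S-shaped
vessels the true maximal wall path switches sides between bends and would
be underestimated.

### Axes and angles

The aortic axis runs from the LVOT-interface centroid to the first
centerline point (the sinotubular junction end); the ventricular axis from
the apex landmark to the mitral-interface centroid. The AoSA is
`arccos` of the dot product of the two unit directions after projection
onto a measurement plane. By default the plane is the one spanned by the
two directions — the projection is then lossless and the angle equals the
direct 3-D angle; an explicit `plane_normal` is accepted for protocols
that prescribe a plane. Angles are reported in [0°, 180°] without
supplementary folding (anatomical AoSA values are obtuse). When no apex
landmark is given, the fallback picks the LV surface vertex farthest from
the mitral centroid — on an elongated chamber this is the apical pole
(within 2 mm on ellipsoid phantoms).

The ascending-aorta inclination is the mean (± SD) over resampled
centerline points with 0 < s ≤ 20 mm of the angle between the chord from
the centerline origin and the aortic axis; on a circular arc this equals
the inscribed-angle closed form s/(2R) on average.

Repeatability emulates the manual protocol: the angle measurement is
re-run `n_repeats` = 5 times with the apex seed perturbed by seeded
isotropic Gaussian jitter of SD `jitter_mm` = 2 mm (the one genuinely
manual point; the other anchors are computed centroids). With the apex
~80 mm from the mitral plane this produces a CV in the ~1% regime, the
same order as careful human repeats.

## Statistics

Sample SDs use the n−1 denominator throughout. The coefficient of
variation is 100·SD/mean of the repeated measurements. Inter-observer
reliability is the two-way random-effects, absolute-agreement ICC —
point estimates and F-based 95% CIs are delegated to `pingouin`, with
both the single-rating ICC(2,1) and averaged-rating ICC(2,k) forms
exposed; an independent variance-components oracle in the test suite
checks the estimates to 1e-9. The F-based interval is an approximation
and can leave [−1, 1] on very small layouts; the wrapper clamps and
orders the bounds and widens them to contain the point estimate, and
collapses the interval when the residual variance is exactly zero.
Pre/post comparisons use two-sided paired t-tests with α = 0.05 and no
multiple-testing correction (a deliberate mirroring of the study design
this package accompanies; with seven endpoints on five patients, readers
should treat individual p-values as descriptive). Percent change defaults
to the signed convention 100·(post − pre)/pre, so increases are positive;
group changes average the per-patient percent changes.

## Phantoms: what the validation shows

The tube phantom sweeps a circular section of radius r along a planar
piecewise straight/arc centerline (arcs all bending the same way), so
length, tortuosity, diameter and both curvature-line lengths have closed
forms. The two-chamber phantom couples a prolate-ellipsoid LV (semi-axes
40/25/25 mm), a 20 mm spherical atrium overlapping the basal pole (their
interface centroid sits on the chamber axis by symmetry), and a straight
aortic tube (radius 14 mm, length 75 mm — ascending-aorta calibre)
anchored on the chamber axis and tilted by the prescribed angle, so the
constructed axis angle is exact. Voxelisation is analytic (point-in-shape
at 1 mm), with a two-voxel sleeve gap between aorta and ventricle labels
so their shared interface is exactly the flat LVOT disc — a planar patch
voxelises without orientation bias in its area-weighted centroid, whereas
lateral staircase contact would bias it by millimetres.

Recovery performance at 1 mm mesh step: all five tube metrics within 0.4%
of closed form across a 12-spec (R, r, θ, straight-length) grid;
constructed AoSA recovered exactly through the mesh route and within 0.8°
through the full voxel route (mask → marching cubes → clip → harmonic →
interfaces → angle), including with the automatic apex fallback. All
phantom constructions are deterministic (bit-identical meshes per spec).

What this does **not** establish: phantoms have exactly circular sections,
no branches, no segmentation noise, no motion artefacts, and planar
same-direction bends. Passing them validates the geometry engine and its
discretisation, not robustness to real CT segmentations; in particular the
branch removal and the openness of the aortic tube are the mask preparer's
responsibility, and curvature lines on strongly non-planar or S-shaped
vessels carry the model caveat above.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `n_levels` | 100 | isolines per vessel (sub-mm spacing on aortas) |
| `samples_per_contour` | 64 | nodes per contour for curvature lines (<0.1% length error) |
| `smooth_window_mm` | 10 | Savitzky–Golay window in arc length |
| `resample_step_mm` | 0.5 | centerline sampling step |
| `aai_window_mm` | 20 | inclination window ("first two centimetres") |
| `n_repeats`, `jitter_mm` | 5, 2.0 | repeated-measurement emulation |
| marching-cubes level | 0.5 | on the binarised label |
| Taubin λ, μ, iters | 0.5, −0.53, 10 | volume-preserving smoothing |

All knobs are recorded in each report's provenance manifest together with
the seed and package version, so a report is reproducible byte-for-byte
from its own metadata.

## Bundled tables

Four small CSVs (five-patient TEVAR cohort) feed the statistics layer:
per-patient AoSA (mean of five repeats ± SD, pre/post, with CVs), the
ascending-aorta geometry per phase, the ten paired two-observer readings,
and cohort characteristics. Values are stored verbatim as printed in their
source, including rounding; recomputed aggregates are therefore compared
at printed precision (±1 in the last printed digit). Known internal
inconsistencies of the source tables (a per-patient percent change and
three pre/post deltas that do not recompute exactly from their own
mean columns) are preserved as printed in the verbatim columns, while
derived quantities are always recomputed from the raw per-patient values.
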