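# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `torsoscan`. It is written for users who need to know
*why* the pipeline behaves the way it does, not just how to call it.

## Problem setting

A handheld camera sweeps around a torso wearing an elastic belt with
`n = 32` electrodes, each covered by a 17 × 17 mm square binary fiducial
marker. From the video frames the pipeline must recover (a) a metric 3D
model of the imaged chest surface and (b) the 3D position of every
visible electrode, accurately enough that no electrode is mislocalized by
one belt place (about 30–40 mm on an adult thorax for a 32-electrode
belt — the displacement at which EIT side-localization breaks down).

Scale is the fundamental ambiguity: multi-view reconstruction determines
geometry only up to a global similarity. Metric units enter through
tape-measured distances between adjacent electrodes on the worn belt.

## Camera model and conventions

Pinhole intrinsics `fx, fy, cx, cy` (pixels), zero skew, lens distortion
assumed corrected upstream. Pixels are `(x, y) = (column, row)`, 0-based,
origin at the top-left pixel *center*. A pose maps world to camera as
`x_cam = R x + t`; the camera looks along +z, image y points down. World
units are meters everywhere inside the library; every report converts to
millimeters at the edge. Intrinsics are a required input: the pipeline
deliberately does not self-calibrate.

## Synthetic scenes (what the generator emulates, and what not)

The torso phantom is a superellipse cylinder
`|x/a|^n + |y/b|^n = 1` extruded along +z. Defaults `a = 0.17 m`,
`b = 0.12 m`, `n = 2.5` approximate an adult chest cross-section; the
validation scenes use a circular phantom of exactly 1 m circumference so
that electrode spacing is the round number 1000/32 = 31.25 mm. A
2^19-sample cumulative chord table gives arc length and its inverse; the
perimeter itself comes from adaptive quadrature (the arc-length speed has
integrable endpoint singularities for `n > 2`, which `scipy` quadrature
handles; tests verify against a 10^6-segment polygonal sum).

The belt places marker centers at equal *arc length* around the
cross-section at a given height — this is how a uniformly stretched
textile belt actually sits. Each marker is a true square of side 17 mm on
the local tangent plane, edges along the horizontal tangent and the
cylinder axis, corners ordered top-left, top-right, bottom-right,
bottom-left in the upright view.

The camera orbit covers a configurable arc (default 100°, matching a
front sweep from one side of the patient to the other) at constant
angular speed, every camera center 0.70 m from the nearest surface point,
optical axis through the phantom axis at belt height. A 360° arc drops
the duplicate end pose. The recording protocol's phrase for this
geometry conflates the arc's "radius" and its angle; it is read here as a
100° arc at 0.70 m range.

Observations are exact projections of marker corners and of seeded random
surface points, with visibility decided by back-face culling only
(normal toward the camera and inside the image); the cross-section is
convex, so self-occlusion culling is unnecessary. Isotropic Gaussian
pixel noise `N(0, σ²)` per coordinate models detection error; σ = 1 px is
the reference noisy condition.

Rendered frames draw each visible marker as its 6×6-cell binary pattern
(black border + 4×4 code + a white quiet zone) perspective-warped by the
exact corner homography, rasterized with 4× supersampled area
anti-aliasing, over a *per-frame* seeded speckle background (30% dark
dot density, lightly smoothed). The background is not attached to the
surface, so rendered frames exercise marker detection and marker-driven
structure from motion, but **not** cross-frame photometric feature
matching; that stage is validated on planar-warp image pairs instead.
Passing tests on rendered scenes therefore demonstrate the geometry
chain, not robustness to real skin texture, lighting, blur or motion.

## Marker dictionary and detection

OpenCV-style 4×4_50 fiducials are used physically; this package carries
its own deterministic 50-code 4×4 dictionary with two guarantees chosen
for decoding at Hamming tolerance 0: the four rotations of a code are
pairwise ≥ 2 bits apart (rotation, and hence corner order, is always
unambiguous), and any rotation of one code is ≥ 4 bits from any rotation
of another. Codes have 5–11 white cells so no pattern degenerates toward
the all-black border.

Detection: local-mean adaptive threshold (block 51 px, offset 0.06),
connected dark components, hole filling, outer contour, polygon
approximation to a convex quadrilateral (escalating tolerance), exact
4-point rectification, 6×6 cell sampling on a 3×3 interior subgrid,
midrange binarization, black-border check, dictionary lookup over the
four rotations. Corners are then refined to subpixel precision: along
each border edge, perpendicular intensity profiles are sampled at
0.25 px steps, the edge crossing is located by the gradient-magnitude
centroid, a total-least-squares line is fit per edge, and adjacent lines
are intersected. The decoded rotation rolls the corner list into
canonical order. Localization degrades gracefully at grazing angles;
decoding simply fails beyond ~55° obliquity, which only reduces the
number of contributing frames.

## Feature tracking

Detection uses an oriented multi-scale corner detector with 256-bit
binary descriptors (scikit-image's ORB), deterministic for identical
input. Matching stacks three filters: Lowe ratio (0.8), mutual best
match, and a seeded random-sample-consensus fundamental-matrix fit with
Sampson distance at 1.5 px. Because a consensus search over unrelated
matches reliably finds ~8–12 chance inliers, a pair is only declared
usable with ≥ 12 inliers covering ≥ 20% of the candidate matches. Tracks
are connected components of the match graph; any component that observes
one frame twice is inconsistent and discarded. In the full pipeline,
keypoints inside detected marker regions are masked out before matching:
fiducials are near-identical to a local descriptor, so they generate
confident matches between *different* markers; marker geometry is
handled by the id-verified marker pipeline instead.

## Structure from motion

Incremental: seed pair → perspective-n-point growth → bundle adjustment.

* **Seeding.** Candidate pairs are ranked by shared track count; each of
  the best 12 is evaluated end to end (essential matrix, pose, two-view
  bundle refinement) and the pair maximizing refined-point-count ×
  median parallax (capped at 30°) wins. The essential matrix comes from
  a seeded RANSAC over the normalized 8-point algorithm with
  larger-than-minimal samples, followed by a nonlinear polish: the 5-dof
  relative pose (rotation vector + translation direction) descends the
  Sampson error from every linear decomposition plus a small-baseline
  seed (identity rotation, translation from median image flow). The
  polish is what makes initialization reliable when the correspondences
  occupy a thin strip (corners along the belt), where the linear
  estimate is badly conditioned. Pose disambiguation is by cheirality
  vote over the four decompositions; the first camera is the identity
  and the seed baseline is normalized to 1.
* **Growth.** The frame with the most 2D–3D correspondences registers
  next via RANSAC perspective-n-point (linear DLT pose on normalized
  coordinates + Levenberg–Marquardt refinement per hypothesis, inliers
  at 2× the reprojection threshold to tolerate oblique marker corners).
  Failed frames are retried after the next bundle adjustment. New tracks
  are triangulated from their registered observations, widest baseline
  first, first estimate passing the gates wins.
* **Bundle adjustment.** Sparse trust-region least squares over all
  poses (first fixed) and points, plain squared reprojection loss,
  terminating on relative decrease < 1e-12 or the evaluation budget; the
  optimizer guarantees a non-increasing objective. Points with mean
  reprojection error > 4 px after the final adjustment are pruned. All
  random-sample consensus draws come from one seeded generator, so runs
  are bit-reproducible.

**DLT triangulation** — the primitive the electrode stage reuses — stacks
the two cross-product constraints of each view into a 4×4 system,
normalizes rows to unit length for conditioning, and takes the smallest
right singular vector. Parallel rays (< 1e-6 rad) and zero baselines
raise a degenerate-geometry error; negative depth sets a cheirality flag.

## Electrode localization

Per frame-pair harmonization keeps only marker ids seen exactly once in
both frames (a duplicated id within a frame cannot be corresponded and is
dropped for that pair). Each of the four corners is triangulated by DLT
per adjacent pair — "adjacent" defaults to consecutive extracted frames,
with a configurable window. Estimates behind a camera or with
reprojection error above 2 px are discarded; the survivors' coordinate-
wise median is the final vertex. Every surviving marker has exactly four
unique vertices (asserted), its center is exactly the corner centroid,
and markers missing any corner are dropped with a warning. Median
merging rather than averaging is an interpretive choice: it is robust to
the occasional bad pair and reproduces a "remove duplicate vertices"
contract without a distance threshold.

Metric scale is the least-squares ratio `s = Σ d_ref·d_rec / Σ d_rec²`
over measured electrode-pair distances, applied jointly to cloud, mesh
and electrodes.

## Surface reconstruction

Densification re-triangulates every track from *all* its view pairs and
fuses the gated estimates by coordinate-wise median — a defined,
testable substitute for patch-based multi-view stereo, chosen so the
error behavior is analyzable instead of opaque. For meshing, only points
observed in ≥ 3 registered frames participate (a 2-view-only point may be
a chance correspondence). The cloud is expressed in cylindrical
coordinates about its principal axis (the covariance eigenvector most
separated from the other two; explicit axis/origin configurable and
recommended when known), binned on a regular (θ, z) grid (defaults
256 × 128), with the per-bin radius the lower median of member radii, a
fixed deterministic rule. Angular gaps of up to 3 bins are filled by
linear interpolation; larger gaps stay holes, so a 100° sweep yields an
open sheet rather than a hallucinated full cylinder. Statistical outlier
removal (mean distance to k = 8 neighbors, 3σ cutoff) precedes meshing.

## Validation

Coarse alignment is the closed-form least-squares similarity (centroid
demeaning, cross-covariance SVD with reflection guard, scale from the
variance ratio). Fine registration is point-to-surface iterative closest
point with exact nearest-triangle correspondences; scale stays frozen at
the coarse value, steps that would raise the RMS are reverted, and the
RMS history is returned so monotonicity can be asserted. Cloud-to-mesh
distances are exact point-triangle distances (kd-tree candidate pruning
with a circumradius-safe refinement radius, so results equal a full
scan), signed positive on the side of the nearest triangle's oriented
normal — the convention under which a reconstruction sitting inside the
reference surface yields a negative mean, which is the only way negative
mean distances in this kind of validation can arise. The maximum is
reported as the maximum absolute distance. The clinical check fails a
reconstruction whose maximum electrode error reaches one inter-electrode
spacing (circumference / n) and warns at half a spacing on the mean.

## Study conditions used by tests and the acceptance script

* Noiseless full chain: 1 m-circumference circular phantom, 32
  electrodes, 17 mm markers, 48 rendered frames on a full 360° orbit at
  0.70 m, 1600 × 900 px at f = 1400 px (a 17 mm marker spans ≈ 34 px).
  The full orbit is used because a 100° sweep physically cannot image
  the far side of the belt; back-face culling reaches ≈ ±129° of belt
  arc, about 23 of 32 electrodes.
* Noisy protocol chain: the same phantom, 21 frames over 100° (the
  handheld protocol), σ = 1 px Gaussian observation noise on id-labeled
  projections, 300 tracked surface points.
* Noise-monotonicity sweeps use a scaled-down 13-frame / 150-point scene
  with a 24 × 4 mesh grid, three seeds per noise level; these sizes keep
  the whole suite's simulations lightweight while leaving the effects
  being measured far above numerical noise.

## Known limitations

* No self-occlusion ray casting in the visibility model; concave
  torso shapes would need it.
* Rendered scenes cannot validate photometric feature matching across
  frames (background speckle is not surface-attached) nor any
  robustness to blur, exposure or rolling shutter.
* The marker dictionary is internally consistent but not bit-compatible
  with any external library's predefined dictionary; physical belts made
  for other dictionaries would need their codes registered here.
* Bundle adjustment uses a plain squared loss; with heavy-tailed real
  detection errors a robust loss may be preferable.
* Cylindrical-grid meshing assumes a roughly cylindrical target; it is
  not a general-purpose surface reconstructor, and makes no fidelity
  claim relative to multi-view-stereo pipelines — only against ground
  truth geometry.
* Mean aggregate statistics across repeated validation runs are reported
  as plain means of per-run values; any other aggregation convention
  must be applied by the caller.
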