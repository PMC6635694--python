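# Methods

This note documents the models, conventions and numerical choices behind
boneframe, and what the synthetic test bed does and does not establish.

## Bones as uniform solids

All analysis treats a bone as the uniform-density (ρ = 1) solid enclosed
by a watertight triangular surface in millimetres.  Volume, centre of
mass and the inertia tensor come from exact surface integrals
(divergence theorem) over the oriented triangles; surfaces are repaired
at load time (duplicate vertices merged, winding fixed, normals made
outward, null faces dropped) and open surfaces are rejected rather than
guessed at, because every downstream step — frames, standardization,
voxel union — needs a well-defined interior.  Segmented bone surfaces
enclose the periosteal boundary, so "volume" here means the envelope
volume; internal porosity is deliberately ignored.

An independent voxel oracle cross-checks the integrals: grid-cell
centres are classified inside/outside by vertical-ray crossing parity
(the grid origin carries an irrational sub-voxel jitter so rays through
edges or vertices have measure zero), and volume/COM/inertia are summed
per cell with the cell's own cube inertia added.  The two routes share
no code; agreement at 0.25 mm pitch is ~0.1% or better on bone-like
solids.

## Body frames

The body frame diagonalizes the inertia tensor.  Axes are ordered by
ascending principal moment: an elongated bone resists rotation least
about its length, so the smallest-moment eigenvector is the long axis
(body x); body y and z follow (for a metatarsal: roughly medial–lateral
and dorsal–plantar).  Eigenvectors have no intrinsic sign, so each of
the first two axes is oriented by the third central moment (skewness) of
the vertex coordinates along it, with two deterministic tie-breaks
(farthest-vertex sign, then largest axis component); the third axis is
their cross product, guaranteeing a proper rotation.  Consequences worth
knowing:

* the frame is deterministic and rigid-motion-equivariant, making
  alignment idempotent and measurements pose-independent;
* handedness is *normalized away*: a mirrored bone lands in the same
  body-frame representation.  Anatomical sidedness (left/right foot,
  which groove is medial) therefore cannot come from the mesh; the
  `flip_sides` option exists for exactly this reason;
* principal moments within a relative gap of 1e-6 (spheres, cubes —
  test fixtures only, no real bone) trigger a warning and a fallback to
  the global axes.

Standardization rescales a subject's three bones by one factor so the
metatarsal's body-frame length equals 100; linear measures scale with s,
areas with s², volumes with s³, so all dimensionless shape ratios are
preserved and subjects of different body size become comparable.  The
packaged measurement table stores post-standardization values (every
metatarsal length is 100.00, surface areas and volumes on the 100-scale).

"Length/width/height" are bounding-box extents along the body axes —
the simplest reading consistent with the packaged table, not calliper
diameters.

## Donor selection

The ratio table divides every (bone, measure) cell by the reference
subject's value; comparisons run at full precision and are *displayed*
rounded half-up to 4 decimals.  The default donor score is the
arithmetic mean of a subject's 15 ratios ("smallest mean value"); a
mean-|ratio−1| deviation score is available as an explicit alternative.
The two orderings genuinely differ on the packaged data: oversized and
undersized bones cancel in a plain mean but not in the deviation, and
the deviation score would rank basketball player 2 (0.1338) ahead of the
runner (0.1505), while the mean-ratio score selects the runner (1.0127,
the smallest).  The mean ratio is the canonical criterion; the
alternative is kept opt-in precisely because of this disagreement.
Ties keep input order with a warning.

## Reconstruction

The damaged bone and the donor are aligned in their body frames.  Two
effects make the raw frame-to-frame overlap insufficient: eigenvector
sign ambiguity (four proper conventions) and the damage itself, which
shifts the damaged bone's COM and axes — losing an epiphysis moves the
COM by several millimetres *along* the shaft, a direction in which ICP
on a near-prismatic diaphysis has almost no gradient.  Initialization
therefore scans sign flips × small rolls about the long axis ×
longitudinal shifts aligning either pair of bone ends, scored by an
untrimmed, normal-filtered mean surface distance (untrimmed so the few
samples on distinctive features count; normal-filtered so samples on
damage cut faces, which lie *inside* the donor, do not).  The best
candidates are polished by a robust point-to-point ICP (Kabsch steps;
untrimmed warm-up, then rejection by 3×median distance and by normal
incompatibility).

The defect is the donor surface farther than `distance_threshold`
(default 1.0 mm, twice the default voxel pitch) from the damaged
surface, grown by 2 mm to close gaps.  Completion happens in a *shared*
voxel grid (default pitch 0.5 mm, matching common CT slice thickness):
the defect region is the set of connected components of
`donor AND NOT damaged` touching the patch neighbourhood — this fills a
missing chunk of any thickness while ignoring the thin mismatch shell an
imperfect rigid overlap leaves elsewhere — and the union is re-surfaced
by marching cubes with light Taubin smoothing.  The whole output is
therefore a re-extracted surface; outside the defect it follows the
original damaged surface to within half a voxel rather than preserving
its exact triangulation (stitching a voxel surface to the original
triangulation was judged not worth its fragility).  With an empty patch
the damaged mesh is returned unchanged.  No shape blending or warping is
applied — the method is overlap-and-borrow by design; how donor and
native surface blend at the rim is purely a consequence of the voxel
union, one reasonable realization among several.

## Groove curvature and parallelism

The metatarsal head's two plantar grooves are modelled as patches of
cylinders.  A cutting plane perpendicular to a cylinder's axis shows a
circle of the true radius; any oblique plane fits a larger circle — so
scanning plane orientations in 0.5° steps and taking the minimal fitted
CD recovers both radius and axis orientation.  (One published
description of this procedure says "maximum CD"; the minimum is the
geometrically correct extremum for recovering a cylinder's radius, and
is the default here, with `scan="max_cd"` available.)

Mechanics of one scan, all in the body frame:

* groove location: coronal sections (normal = long axis) are swept along
  the bone; concave runs of the resampled contour's signed curvature
  (threshold −0.05 mm⁻¹) are classified relative to the contour
  centroid; the side (±v) carrying more concave arc length is the
  plantar side, and the two longest concave runs there are the grooves,
  labelled medial/lateral by the u-sign of their centroids.  Contour
  resampling and curvature smoothing scale with the contour perimeter
  (≥ ~400 samples) so small bones are not undersampled.
* per angle, the section plane contains the vertical axis, pivots on the
  groove-arc centroid, and is rotated about that vertical line.  The arc
  is trimmed (12% per end, where smoothing bleeds into the convex
  shoulder), then symmetrized about the groove *vertex* — the arc point
  opposite the plantar opening, which unlike the run endpoints does not
  move with detection noise — and a circle is fitted (Kasa algebraic
  least squares; exact on true circles, 3 points give the circumscribed
  circle).  Because a cylinder is translation-invariant along its axis,
  the CD at each angle is averaged over five parallel planes spread over
  ± half the groove radius: discretization noise decorrelates between
  planes, the signal does not.
* the CD-vs-angle curve near its optimum is a shallow parabola
  (r/cos²ε), so the raw arg-minimum jitters by 2–3 steps under
  mesh-discretization noise.  A quadratic fitted to the trace within
  ±3° of the raw minimum gives a continuous vertex estimate; the
  reported `rotation_angle` is that vertex, while the reported CD is the
  definitional extremum over the scanned trace.  Without this
  refinement, parallelism verdicts at the 0.5° tolerance would be
  dominated by grid quantization (two independently snapped angles can
  differ by a full step for identical axes).

Parallelism: the grooves are parallel iff their min-CD rotation angles
agree within the tolerance (default 0.5°, the scan's angular unit).
Both fits must come from the same scan configuration; the equivalent
"one section is a circle while the other is an ellipse" criterion is
implied by the angle comparison and not implemented separately.
Positive angles are counter-clockwise looking down the rotation axis
(`clockwise_positive` flips the sign convention for display).

The base-level search (largest cross-section among planes *containing*
the long axis) is a separate, simpler scan with ties resolved to the
smallest angle.  Note a geometric subtlety: for a box-like solid the
maximal such section is the diagonal plane, not the largest face.

## Synthetic test bed

The generator builds bone-like solids as a signed-distance CSG field —
an elliptical-capsule shaft with a proximal flare (taper 0.2; long bones
are wider at the base, and the flare also makes rigid registration
longitudinally well-posed, which a pure capsule is not), a spherical
head, and two finite-cylinder grooves of chosen radius and skew
subtracted on the plantar side — sampled at pitch `head_radius/40` and
extracted by marching cubes at level 0.  A continuous field keeps the
surface sub-voxel accurate, which matters because CD recovery is tested
at 3%.  Ground-truth volume counts interior grid cells of the same
field; groove CDs and axis angles are the construction parameters,
mapped into the bone's actual body frame
(`groove_truth_in_body_frame`) because the inertial frame tilts ~1°
relative to the construction frame (the grooves shift plantar mass) and
may flip axis signs.  An optional smooth seeded surface undulation
(`surface_noise`) makes seeds distinct individuals for mass-property
tests; it defaults to 0 because noise of amplitude comparable to the
CD tolerance would confound groove tests.

The damage operator removes a prescribed volume fraction in the voxel
domain (plane clip positioned by a quantile of projections, or a
sphere bite with bisected radius) and re-extracts a watertight surface.

Problem sizes used by the test-suite and the acceptance script — groove
sweeps over radii {2, 4, 8} mm × skews {0, 1, 2, 5}°, ten seeds per
parallelism condition, ten random bones for the mass-property oracle at
0.25 mm pitch, ten damage seeds at 5–30% removed volume — were chosen to
cover the parameter ranges of interest while keeping a full run in the
minutes range.

What passing these tests shows: the geometry pipeline (frames,
sectioning, arc detection, circle fitting, scanning, voxel completion)
recovers known ground truth on clean, watertight, single-component
surfaces.  What it does not show: robustness to segmentation artefacts,
handles/holes, partial voluming, cortical-thickness effects or
anatomical variation beyond the generator's shape family — real CT
material should be inspected with the SVG section exports before
trusting automated labels.

## Known limitations

* Medial/lateral labelling is conventional (see body frames); real
  applications must set `flip_sides` from anatomical knowledge.
* The completed surface is voxel-born everywhere (half-voxel fidelity to
  the preserved surface) rather than preserving the input triangulation
  outside the defect.
* Groove detection assumes two clearly concave plantar arcs in the head
  region; ridges worn flat or grooves shallower than the curvature
  threshold (−0.05 mm⁻¹) will raise a groove-not-found error rather than
  degrade silently.
* The inertia-based frame assumes the mesh encloses the whole bone; a
  partial bone's frame differs from its intact twin's, which the
  reconstruction's registration step compensates but pure frame overlap
  would not.
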