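# Methods

This note records the models, conventions and numerical choices behind
`mandrec`, and what the synthetic test bed does and does not establish.

## Coordinate conventions

All geometry is in millimetres, in a patient-space RAS-like frame: +x to
the patient's right, +y anterior, +z superior. The median (sagittal)
plane of a perfectly symmetric mandible is x = 0. The mandibular midline
is parameterized by arc length `s`, with `s = 0` at the right condyle and
increasing to the left condyle; "the midline" always means this
condyle-to-condyle centerline curve, distinct from the median plane.

## Reference model

The reference is a canonical mandible carrying the annotations the
pipeline needs: 14 named landmarks, the midline polyline, four zone
boundaries partitioning the midline into {H_right, L_right, C, L_left,
H_left}, a per-sample lateral (outward) direction field, rigid reference
points for transplant positioning, and the available vertical height of
the tooth-bearing body (`apical_offset`, with `basal_offset = 0`).

Rather than shipping a mesh file, the canonical reference is generated
deterministically at first use from the fixed parametric mandible
(default specification, seed 0); `registration.save_reference` /
`load_reference` export and re-import it as PLY + JSON for users who want
the asset on disk. Generation is byte-reproducible, so this is equivalent
to a bundled asset while keeping the distribution pure source.

The 14 landmark names (pogonion, gnathion, paired mental foramen, canine
point, gonion, antegonial notch, coronoid tip, condylion) are a package
convention: a fixed, roughly evenly distributed set covering chin, body,
angle and ramus, chosen so that left/right pairs support median-plane
estimation and the canine/antegonial sites define the classification
zones (C spans canine to canine; the H/L boundary sits at the antegonial
notch per side).

## Synthetic anatomy

The generator emulates the clinical inputs (segmented bone meshes) with
the simplest shapes exposing every feature the pipeline consumes.

**Mandible.** An elliptical cross-section (semi-height = body_height/2,
semi-width = body_height/4) swept along a centerline composed of a planar
240° body arc, rounded gonial corners (quadratic Bezier blends), and
near-vertical rami that lean outward just enough to honor the requested
intercondylar width; condyles are closed with spherical-ish caps. The
sweep frame uses the horizontal radial direction as its first axis, which
is well defined along the whole path and makes the construction exactly
mirror-symmetric at `asymmetry = 0`. A seeded surface jitter of 0.02 mm
(normal, per vertex, along the ring radial) makes distinct seeds produce
distinct meshes without disturbing symmetry or landmark placement;
landmarks are mesh vertices, hence exactly on the surface. `asymmetry`
in [0, 1] smoothly inflates the right side by up to 8%.

Defaults (body arc radius 30 mm, body height 25 mm, ramus height 55 mm,
intercondylar width 100 mm) give a ~246 mm condyle-to-condyle midline,
in the range of adult anatomy. Mesh resolution defaults to
0.25 vertices/mm² (~4.4k vertices), dense enough that vertex-sampled
surface distances track true surface distances at the 0.1 mm level.

**Fibula.** A circular tube (default length 240 mm, diameter 12 mm),
straight or gently bowed (circular arc of curvature κ), with an analytic
lateral-face direction field at a configurable azimuth and a vessel
polyline offset medially (opposite the lateral face) by `vessel_offset`.
The full length is treated as harvestable.

**Defect scenarios.** Ground-truth cut planes are placed from the zone
boundaries: classes L, C, LC, LCL use two cuts; H and HCL use a single
cut with the condylar end of the affected side resected
(hemimandibulectomy-like). Spans default to class-typical values and are
validated against the zones; unconstructible requests raise. The round
trip scenario → planes → classification is exact by construction and is
verified over seeded sweeps.

**What the synthetic bed does not show.** Real mandibles have coronoid
and condylar processes, teeth, cortical/trabecular structure, and
pathology-driven deformation; segmentations carry noise and topology
defects. Passing tests demonstrate the pipeline's geometric and
algorithmic correctness on clean, watertight, quasi-symmetric anatomy —
not robustness to segmentation artifacts or anatomical extremes.

## Registration

Elastic registration is an interpolating 3D thin-plate spline with kernel
`U(r) = r` (the 3D biharmonic solution) plus an affine part, solved from
the named landmark correspondences; smoothing defaults to 0, so control
residuals are at round-off (< 1e-6 mm with huge margin). At least six
non-skipped pairs are required; fewer raises an explicit error naming the
count. Coplanar control configurations (condition number of the
homogeneous control matrix > 1e8) are refused rather than producing an
unidentifiable affine part. The same transform warps the mesh, midline,
landmarks and rigid points; direction fields (lateral markings) are
pushed through by 0.5 mm finite differences and re-normalized; zone
boundaries travel with their midline sample positions (interpolated on
old vs new cumulative arc length). The median plane for mirroring is
estimated from the left/right landmark pairs: normal = dominant singular
vector of the difference vectors, anchor = centroid of the midpoints.

The spline family agrees with SciPy's `RBFInterpolator(kernel="linear",
degree=1)` to ~1e-14; that implementation serves as an independent
cross-check in the tests, never as the implementation.

## Resection and classification

Cut snapping projects the raw anchor to the nearest midline point and
takes the local midline tangent as the plane normal ("perpendicular to
the bone" is read as orthogonal to the bone's long axis; a literal
surface-normal reading is ill-defined for a through-cut). User rotations
are stored relative to the tangent-aligned frame so that moving a rotated
cut along the midline preserves the rotation, and move/rotate operations
invert exactly. Anchors farther than 40 mm (configurable) from the
midline are rejected.

Mesh partitioning slices with trimesh and closes each cut cross-section
by ear-clipping its boundary loops in the cut plane (slice vertices are
welded first so the boundary chains into closed loops). Because the
mandible is horseshoe-shaped, an infinite plane through one side can also
intersect the contralateral side; like a finite saw blade, the cut takes
effect locally: the mesh is partitioned by all planes, split into
connected components, and each component is attributed to resected or
residual by the midline arc position of its centroid. Volumes are then
conserved to machine precision.

Classification collects zone letters intersected by the defect interval
right-to-left, with H absorbing L on the same side and C emitted once,
then canonicalizes to the side-agnostic clinical label (letter order
H < L < C between a string and its reversal), so left- and right-sided
lateral-central defects are both reported as "LC" and hemimandible +
central + contralateral lateral as "HCL". One-cut plans define the
defect interval from the cut to the resected midline end.

## Variant knowledge base

Variants live in `data/variants.yaml` (axes: donors, pedicle sides, skin
islands; feasibility predicates by name) so the inventory can grow
without touching the algorithms. Segment counts range from
`ceil(arc / max_segment_length)` to `min(max_segments,
floor(arc / min_practical_segment_length))`; defaults 40 mm, 15 mm and 4
segments are planning conventions exposed in the configuration.
Mono-segment variants on defects spanning multiple zones (e.g. across the
gonial angle) are controlled by `allow_mono_segment`, default on —
surgeons expect a standard mono-segment option for short defects. Skin
islands may not sit on the medial face (that face carries the vessels);
the default inventory carries `none` only, with the island orientation as
metadata (no soft-tissue geometry).

## Chain optimization

Chain endpoints are the intersections of the warped midline with the
resection cut planes (for one-cut plans, the free end of the defect
interval, with the end-tangent plane as a synthetic terminal). Interior
knots are restricted to the warped midline, discretized at
`midline_step` (default 0.5 mm).

The discrete stage is an exact search over all strictly increasing
interior-knot placements: per-pair segment tables (summed sample-to-
segment distances, chord lengths, projected-outward lateral directions)
are precomputed once, and all combinations (at most three interior knots
for the four-segment cap) are evaluated vectorized in blocks. This is
exhaustive enumeration made affordable by staged prefix accumulation; a
plain dynamic program would be exact only for additive objectives,
whereas the score's exponentials and junction terms are not additive.
Ties break to the lowest knot indices, making results deterministic. A
continuous polish then runs coordinate descent on the interior arc
positions with step halving from `midline_step / 2` to 0.05 mm.

Scoring (all components in [0, 1], total = weighted mean over criteria
with positive weight):

- **Midline fidelity** `exp(-d̄/τ_m)`, τ_m = 5 mm, where `d̄` is the mean
  distance from the defect midline samples to the chain, with samples
  matched to segments by arc interval (between consecutive knot
  positions). The interval matching is what makes the objective
  decomposable over segments for the pair tables.
- **Symmetry** `exp(-d̄/τ_s)`, τ_s = 5 mm, against the contralateral
  midline mirrored across the estimated median plane (sample at `S - s`,
  reflect, compare to the chain) — quasi-symmetry of the mandible makes
  this a proxy for the pre-morbid shape.
- **Surface continuity**: mean over junctions of `max(0, cos θ)` between
  adjacent lateral-face directions. For a planar chain rolled outward
  this equals the cosine of the bend angle, penalizing sharp mitre
  corners that break the lateral surface.
- **Pedicle feasibility**: 1 while the pedicle-end knot is within
  `pedicle_max_length` (default 80 mm) of the anastomosis-side gonion
  rigid point, then `exp(-(d - max)/20)`. Independent of interior knots,
  so it never influences knot placement.

The functional forms and constants are package conventions (exposed in
the configuration); the criteria themselves — midline/morphology,
symmetry, lateral surface, vessels/pedicle — are the clinically named
analyses. Zero-weight criteria are excluded from the normalization; an
all-zero weighting is an error.

## Harvest, orientation, level

Harvest intervals are allocated contiguously from the pedicle-proximal
end of the donor fibula with a 1 mm saw kerf between intervals
(configurable). The recipient chain runs right to left; a left-sided
anastomosis reverses the segment-to-interval mapping so the vessel end of
the strip lands next to the pedicle side. Intervals are checked against
the harvestable length, with the shortfall reported in mm.

Each segment's roll about its axis aligns the fibula's lateral-face
direction with the outward target (away from the dental-arch centroid,
projected normal to the axis). If the vessel line would end up lateral,
the roll backs off to the nearest vessel-medial orientation and a warning
is recorded; with the default synthetic fibula (vessel exactly opposite
the lateral face) the two conditions never conflict.

Transplant level translates tooth-bearing knots (midline position inside
the body zones) along the local vertical (lateral x tangent of the warped
reference): basal = 0, apical = `apical_offset - fibula_diameter`,
middle = half that. Terminal knots have the translation projected into
their cut plane, so the seamless-connection contract survives leveling.

## Refinement

All operators are pure (copy, modify, recompute osteotomies, harvest,
orientation, warnings, score). Terminal junction edits are projected
onto the cut plane; zero-length segments are rejected while short ones
only warn. `rotate_transplant` is a rigid rotation about the line
through the terminal knots (lengths preserved exactly). Cut-plane edits
rebuild the resection (re-cut, re-classify) and re-project the chain
endpoints; by default interior knots are preserved, and with
`reoptimize` the engine evaluates both the re-run optimizer and the
preserved warm start and keeps the better — so re-optimization can never
lose to preservation. Action journals (YAML) replay deterministically.

## Numerical choices and degenerate inputs

- Interpolating TPS: residual tolerance 1e-6 mm (measured ~1e-14).
- Miter bisector: normal = normalized sum of adjacent unit axes;
  anti-parallel axes are a hard error (degenerate miter).
- Snapping idempotence and move/rotate inverses hold to 1e-9.
- Ear clipping falls back to fan triangulation for numerically flat
  remainders; cut cross-sections of tube-like bones are near-convex.
- Knot ties in the optimizer break to lowest indices; refinement accepts
  improvements only beyond 1e-15 to avoid float chatter.
- Empty defect intervals, non-intersecting cut planes, out-of-domain cut
  moves (clamped with a warning) and unconstructible scenarios raise
  explicit errors.

## Problem sizes used in tests

The test suite and the acceptance script run on the default synthetic
sizes: ~4.4k-vertex mandibles, defects of 26-160 mm, optimizer grids of
0.5 mm (5 mm for the brute-force equivalence checks, where the naive
oracle enumerates every placement), 50-100 seeded scenarios for sweep
properties. These sizes were chosen so the whole pipeline — including
mesh cutting and exhaustive enumeration — exercises every code path at
interactive speed.

## Known limitations

- The reference is a parametric idealization, not a population mean
  shape; registration quality on real anatomy is untested here.
- Segment geometry is modeled as straight prisms of circular
  cross-section; the real fibula is triangular-prismatic and slightly
  twisted, which affects cut-guide manufacture but not the chain
  geometry.
- Scoring constants (τ = 5 mm, pedicle 80 mm) are conventions, not
  clinically calibrated values.
- One-cut (condyle-sacrificing) plans synthesize the free terminal plane
  from the midline end tangent; prosthetic condyle handling is out of
  scope.
- No soft tissue, plates, cutting guides, dental implants or
  biomechanics.
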