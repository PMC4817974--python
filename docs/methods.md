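# Methods

This note records the models, conventions, parameter choices and known
limitations behind gutmorph's implementation.  Everything quantitative
stated here is computed by the test suite or the example scripts.

## Coordinate and angular conventions

The embryo frame places the tube axis along +x (anterior at small x),
dorsal along +z and the animal's right side along +y.  Circumferential
position θ is measured in degrees from the dorsal midline, range
(−180, 180], **positive clockwise as seen from the anterior end**
(camera anterior, looking posteriorly, dorsal up).  In that view the
animal's right appears on the screen's left, so R-side cells occupy
θ ∈ (−180, 0) and L-side cells (0, 180); ±180 is the ventral midline.
This is the unique assignment under which all the motion descriptors are
simultaneously consistent: the wild-type rotation of rings 2–4 is a
positive (clockwise) Δθ that carries the R cells across the dorsal
midline toward the left; the pre-rotation shift takes 2L's ventral
boundary clockwise past +180; and in mode-2 int2 closure 2R's dorsal
extreme crosses θ = 0 onto the left side.  Mirrored conventions are a
classic sign-bug source, so `tests/test_geometry.py` pins the convention
(`to_cylindrical` of a point 90° clockwise of dorsal is +90; R-side
surfaces carry negative θ in the symmetric fixture).

The tube axis is fitted as the moving-average-smoothed polyline through
per-ring centroid means; any smooth centerline within 0.5 µm of the ring
centroids is acceptable since only angular *differences* enter the
analyses.  The dorsal midline is defined geometrically by a reference
vector orthogonalized to the local tangent — the original measurements
located it by hypodermal landmarks, which a synthetic tube does not have.

## Synthetic primordium

**Geometry.** Cells are curved prisms: trapezoids in the unrolled (θ, x)
plane, extruded radially between r_out = C/2π and r_out − t.  Defaults:
circumference C = 47 µm (the measured E16–E20 value — the only cell-scale
dimension reported), ring height 2.5 µm and radial thickness t = 3 µm,
chosen so that 20 cells tile a shell of plausible E16 proportions
(cells ~20 µm of arc by 2.5 µm by 3 µm, ~130–150 µm³).  No stage-specific
dimensions are asserted; all are spec parameters.

**Diagonal packing.** Each inter-ring interface carries two three-cell
junctions, one near θ = 0 (dorsal) and one near ±180 (ventral).  A
junction's configuration is encoded by a signed boundary offset of
magnitude s = 15°: for RaL the posterior ring's R/L boundary is offset
so the R cell covers the junction arc of the anterior L cell (clockwise
past the anterior boundary at the dorsal junction, counterclockwise at
the ventral one); LaR is the mirror; zero offset leaves a four-cell
vertex (Cross).  Sampling the two junctions independently per interface
reproduces every observed pair category, including RaL+RaL with two
geometrically distinct contact faces (the hexagonal-packing signature)
and the invariant RaL+LaR between int2 and the divided int1 (2R–1LD,
2L–1RV; int1's four daughters are its R/L halves split at θ = ±90).
A single scalar "offset the whole boundary clockwise" encoding cannot
produce a pure RaL interface — with straight axial boundaries one offset
always creates one RaL and one LaR arc — which is why the junctions are
parameterized separately.  Default junction probabilities (0.8, 0.1,
0.1) reflect the strong RaL bias scored at hatching; the E8 plate
generator defaults to the early bias toward LaR (0.04, 0.91, 0.05).

**Trajectories.** Morphogenesis is kinematic.  Scheduled events:
rigid ring/cell rotations about the axis (angle linearly ramped between
onset and end; volumes exactly conserved); the pre-rotation shift of the
int2 ring (default +12° from 289 min); int2 intercalation/closure from
329 min starting from a dorsal gap of 25° per side — in mode 1 both
cells rotate to meet at the dorsal midline, in mode 2 2L stalls 10°
short and 2R rotates clockwise past the midline to close the ring (the
closure targets are absolute angles, so a completed pre-rotation shift
is compensated); the int5 anterior–posterior exchange (a stylized 0.3 µm
axial nudge — kept below the 0.5 µm contact threshold so a rigid
translation does not artificially sever the transverse contacts that
deforming cells would maintain); and junction conversions that
interpolate a junction's offset continuously toward a target
configuration (the post-E8 LaR→RaL transition).  The canonical wild-type
schedule converts the posterior interfaces over 257–297 min and the
int3/int4 interfaces over 289–329 min, rotates rings 3–4 by 90° cw over
337–433 min and ring 2 over 361–433 min, and samples frames every 8 min
(the reconstruction's imaging interval) from 249 to 441 min.
Contradictory overlapping events for the same cells are rejected at
schedule construction.  The planar-E8 → bilayer-E16 transition and the
int1 division are not meshed as continuous deformations: E8 is a
separate planar-plate generator and the 4-cell int1 appears in the
static larval fixture.

**Voxelization and rendering.** Label stacks default to the acquisition
geometry (49 Z-slices at 0.5 µm; 0.2 µm xy pixels, a typical 60×
sampling — the actual xy pixel size was not reported, and the value is
recorded in the sidecar).  Voxels are assigned by parity-fill ray
casting per (y, x) column; the grid origin carries an irrational
sub-voxel offset because a real microscope grid is never aligned with
the cell geometry — without it, voxel centers can sit exactly on the
idealized boundary planes and whole interface layers collapse onto one
of the two adjoining cells (a ±4 % volume artifact).  Membrane rendering
deposits subdivided-face areas with trilinear (cloud-in-cell) weights,
so adjoining membranes add and a line scan across a two-membrane
interface peaks at ~2× a single surface; optional Gaussian PSF blur and
surface jitter emulate optics and tracing noise.  The doubling ratio is
only meaningful on blurred images (unblurred peaks are voxel-alignment
artifacts), so the rendering tests use psf_sigma = 0.3 µm.

What the generator does *not* emulate: cell mechanics, adhesion,
deformation during events (all motion is rigid), division, imaging
shot/detector noise, depth-dependent attenuation, or deconvolution
artifacts.  Passing tests therefore demonstrate correctness of the
*measurement* pipeline on geometry with known answers, not robustness to
every property of real confocal data.

## Shadow contact areas

The optical construction — omnidirectional light calibrated on two
E16-scale cubes separated by 0.5 µm until the shadow vanishes — is
re-expressed as thresholded, orientation-aware surface area: a surface
element of A is shadowed by B when (i) its distance to B's surface is
below the calibrated threshold (strictly: the calibration endpoint
itself casts no shadow) and (ii) the closest point of B lies on the
element's outward side (n_A · (closest − p) > 0; coincident surfaces
fall back to requiring opposed normals).  Condition (ii) is what the
light box enforces physically — geometry behind or beside a surface
element cannot darken it — and removes the flanking strips a bare
distance cut would count; formulating it via the closest-point direction
rather than the nearest triangle's normal makes the decision independent
of which coplanar triangle happens to be nearest (tie-breaking on
creased meshes otherwise flips whole strips).  Faces are subdivided to a
0.25 µm maximum edge (half the threshold) before accounting, bounding
the area quantization error at a few percent on fixtures.

The ray-cast variant implements the construction literally: deterministic
Fibonacci-sphere ambient directions, a face shadowed when its occluded
outward fraction exceeds a cutoff calibrated as the maximum occlusion
observed at the 0.5 µm cube separation.  It reproduces the calibration
endpoints (zero at 0.5 µm, the full face in contact) but differs from
the distance form at intermediate gaps, where "shadow" becomes
penumbral; the distance form is the primary implementation because its
observable matches the thresholded shadow images.  The brute-force
`proximity_oracle` covers A with a deterministic barycentric lattice
(≥ the requested density per µm²) and tests every triangle of B, sharing
neither the spatial prefilter nor the subdivision machinery.

The intensity value of the original light box and the shadow-image
threshold were never reported; only the calibration endpoint is, and
that is exactly what `calibrate()` pins.

## Packing classification

A junction is called Cross when all four cells approach a common point
within ε = 0.25 µm (half an optical section).  The vertex test takes
precedence over the area comparison: at a true four-cell vertex both
diagonals carry small edge-adjacency bands that would otherwise win on
area.  Otherwise a diagonal is present when its zone-restricted contact
area exceeds 0.05 µm² (a few subdivided faces — the original scoring was
visual and reports no threshold); if both diagonals exceed it the larger
wins and the margin is logged.  Whole-surface mode reports both
junctions; roof-plane mode restricts to a 0.5 µm slab one optical
section below the dorsal-most surface, which sees only the dorsal
junction — matching single-plane time-lapse scoring, with a per-frame
flag for within-ring partners separating from the roof.

## Rotation quantification

Boundary angles are the endpoints of the R cell's angular extent (the
complement of the largest empty gap among vertex angles), which coincide
with the ring's R/L boundaries when the ring is closed and with the
cell's free edges across the pre-closure int2 gap.  Traces are anchored
to (−180, 180] at the first frame and unwrapped assuming < 90° motion
per 8-min frame (safe by ~7× at the observed 0.1–0.2 µm/min).  The int2
event detectors read extents in each cell's anterior third, which
isolates the cell-body boundary from packing-driven boundary slants at
the int2/int3 interface; closure mode is decided by where the dorsal gap
closes (at the midline → mode 1; past it on the left after 2R crossed →
mode 2), and the trajectory must actually cover the pre-closure stage,
otherwise the flag is "undetermined".

"Full rotation" has no numeric definition in the source; the package
calls a ring full when its leading boundary has advanced at least 45°
past the dorsal midline in its direction of motion by the end of the
393–441 min window, which cleanly separates full from partial
interdigitation on the fixtures; partial requires ≥ 15° net motion.
Sector extents (bz1 ±15°, muscles 15–75°, bz2 75–105°, seam 105–135°,
ventral hypodermis 135–160°, ventral neurons 160–180°, mirrored on the
right) are package defaults — none were measured — and are configurable
and written into every report that uses them.

## Statistics

Fisher's exact test (two-sided hypergeometric) compares contact
populations after collapsing multi-category calls to RaL vs non-RaL:
with 15–36 scored contacts per stage an exact test over six categories
is not informative.  The collapse is configurable and recorded.  Star
levels: one star p < .05, two stars p < 5·10⁻⁴.  No multiple-testing
correction is applied by default, matching the source presentation.
Volume trends use per-cell linear slopes with a two-sided permutation
p-value (999 seeded permutations); a trajectory is "flat" when no cell
is significant at α = 0.05.

## Numerical choices and limitations

- Point–triangle distances use the standard region-based closest-point
  algorithm with a cKDTree candidate prefilter plus an AABB pre-cut;
  the brute-force path exists independently for validation.
- Parity-fill voxelization nudges triangles by a sub-nanometre
  irrational offset so voxel-center rays never pass exactly through
  shared edges; odd crossing counts (degenerate grazing) are dropped.
- Mesh volume/area use the divergence theorem on watertight meshes; the
  curved prisms chord the cylinder at ≤ 4° per segment (volume error
  < 0.5 % against the analytic ground truth).
- Analyses assume one mesh per cell per frame and no contact tracking
  across frames; areas and calls are per-frame quantities.
- The classifier's zone split (dorsal junction |θ| < 90°) assumes
  junctions stay within their hemicircles; after large rotations the
  ring-pair calls of rotated interfaces should be read in the rotated
  frame (the rotation analyses, not the packing table, are the intended
  measurements there).
- Problem sizes in the tests (tube resolution, frame counts, oracle
  densities, permutation counts) are chosen to exercise every property
  at comfortable numerical margins on a single CPU.
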