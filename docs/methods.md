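# Methods

## The problem

Pelvic bone tumor resection with a patient-specific cutting guide (SCG)
chains several numerically distinct problems: multimodal image alignment
(bone reads best on CT, tumor on MR), segmentation, surface reconstruction
and simplification, resection planning under an oncologic margin
constraint, constructive solid geometry for the guide itself, and
quantitative verification. This package implements that chain end to end
and treats the *margin guarantee* — after planning, the minimum 3D distance
from the tumor surface to every cut surface is at least the prescribed
oncologic margin — as the central invariant the whole pipeline must
deliver.

## Synthetic phantoms

Real pelvis CT/MR cannot ship with a package, so every stage is exercised
on seeded synthetic cases. The bone is a stylized hemipelvis assembled from
implicit primitives chosen to reproduce the *topological* traps of the real
anatomy rather than its shape: a thin (6 mm) iliac-wing plate with a free
crest edge (tests the deformable clip), an acetabular cup shell, an
ischiopubic torus whose opening stands in for the obturator foramen, and a
sacral block pierced by two Ø8 mm foramen-like tunnels (both give the bone
genus > 0 and interrupt guide trajectories, which the builder must bridge).
Four ellipsoidal tumors (default radii 16 × 13 × 10 mm, seeded jitter ±1.5
mm and up to 12° rotation) cover the Enneking zones; the bone is unioned
with a thin capsule around the lesion so the tumor is a bulging, fully
contained mass. Meshes come from marching cubes over the signed field
sampled on an off-lattice grid (flat primitive faces would otherwise hit
exact zeros and degenerate the triangulation); equal (case, seed, params)
reproduce bit-identical arrays.

Tumor sizes are free parameters: no source dictates them, and the defaults
were chosen once as a plausibly resectable lesion large enough to force
multi-plane cuts.

### Intensity model

Pseudo-CT orders bone (1200) ≫ tumor (400) ≫ background (0); pseudo-MR
inverts the contrast (tumor 900 ≫ bone 250 > background 60). Gaussian noise
(sd 20 by default) is added on top. Two deliberate departures from a plain
three-level model:

- **Trabecular-like texture.** A smooth deterministic texture (sum of 12
  seeded cosine waves, wavelengths 8–16 mm, unit RMS, per-tissue gain) is
  added inside bone and tumor, *identically placed* in CT and MR because it
  is anatomy and deforms with the tissue. Without it the registration
  problem is ill-posed: motion tangential to a piecewise-constant surface
  is invisible to any intensity metric, and no optimizer can recover it.
  Setting `texture_amplitude = 0` restores the exact three-level model.
- **Known deformation.** The MR is synthesized by evaluating the anatomy at
  y + v(y), where v is a cubic-interpolated random field on a 24 mm control
  grid scaled to a 3 mm maximum. Because v is coarse and small, id + v is a
  contraction, so the fixed→moving map (the resampling convention) is
  obtained exactly by fixed-point iteration; the ground-truth transform
  therefore supports both directions to machine precision and serves as the
  registration oracle.

## Volume processing

World frame is LPS millimetres everywhere; volumes store
`world = origin + direction @ (spacing * index)` with values at voxel
centers, and files read back through a canonical-orientation normalization
that leaves world coordinates unchanged. Registration is multi-resolution
free-form deformation (B-spline, 3 levels, final control spacing 25 mm)
under Mattes mutual information with seeded random sampling (20%) and an
LBFGS optimizer — multimodal-safe and deterministic for a fixed sampling
seed. Non-convergence is defined operationally: the final metric must not
be worse than the initial one, else the call raises with both values.

Watershed runs on the Gaussian gradient magnitude (σ = 0.7 voxels; larger
smoothing biases the basin boundary and costs Dice at thin structures).
Marker automation reflects expected volume fractions: bright-structure
seeds are eroded percentile thresholds (bone p95 on CT, tumor p99.5 on MR —
the tumor is well under 1% of the field of view), background seeds are the
volume border *plus* eroded dark voxels so the background basin can reach
foramen interiors, and `band_markers` seeds intermediate-intensity
structures for the mono-modal (CT-only) route. Measured on the phantoms:
noise-free CT bone Dice 0.997, noisy deformed-MR tumor Dice 0.994,
registration landmark error ≈ 0.7 mm mean against a 3 mm ground-truth
deformation (sub-voxel at 1 mm CT spacing).

## Mesh processing

Decimation is quadric edge collapse with the merged vertex at the
quadric-optimal position, iterative error thresholds, normal-flip
rejection, locked boundary vertices and an explicit link condition (the
common neighbors of an edge's endpoints must be exactly the two shared-face
apexes), which preserves the Euler characteristic of closed meshes. Closed
manifold meshes have even face counts and interior collapses remove faces
two at a time, so even targets (e.g. 100,000) are met exactly; a 2.7M-face
bone decimates in ~30 s. Hausdorff distances are exact point-to-surface
distances sampled on all vertices; a vertex KD-tree gives per-query upper
bounds and only triangles whose centroid can beat that bound are tested, so
the result equals the brute-force O(V·F) scan (asserted against an
independent oracle in the tests).

## Planning

The approach plane is defined by three points (right-hand-rule normal = the
surgical approach). The tumor silhouette is the union of all projected
triangles (outer ring; interior holes discarded — a hole in the projection
cannot relax a margin). The margin budget folds the blade kerf into the
offset: total = oncologic margin (10 mm) + blade thickness (2 mm) = 12 mm.
Polyline fitting places each of the 1–4 segments on a support line of the
convex hull of the offset polygon facing the resected side, which
guarantees by convexity that every polyline point keeps at least the
planned offset from the silhouette; endpoints extend beyond the projected
bone extent so cuts are through-cuts.

Extrusion tilts each surface by the draft angle so the cut plane creeps
*toward* the piece with depth — the resected cork tapers and extracts
along the approach; the opposite sign would wedge it. Because that taper
consumes margin at depth, `validate_plan` measures the true 3D
tumor-to-surface minimum (dense area-weighted surface sampling plus the
exact tumor-vertex minimum) and pushes violating segments outward in 0.5 mm
steps (max 20); per-segment margin overrides (e.g. local 5 mm reductions
for bone stock) are honored. Adjacent extruded planes intersect in an
exact junction line, later reused for corner gaps.

## Guide generation

The trajectory is the bone∩cut-surface intersection restricted to the
approach-facing side of the bone (face-normal filter), clipped to each
surface's active region by its neighbor planes, reduced to the
approach-facing envelope where several bone layers stack, and windowed to
the tumor's extent along the cut ± 20 mm — through-cuts cross the whole
bone, but the guide only spans the region the surgeon works in. Chains are
smoothed by a least-squares spline (deviation < 0.5 mm, verified), then
projected back onto their exact cut plane. Nodes are the two extremities
plus every junction crossing; gaps (foramina, or junctions the bone surface
never reaches) are bridged by straight spans that carry main body only, no
guiding flange. Fragments shorter than 3 mm are dropped; the build fails
only if the total on-bone trajectory is shorter than one anchor radius.

Bodies are exact parametric meshes (parallel-transport sweeps, icospheres,
prisms, annular tubes), so every printed dimension can be measured back
from geometry to machine precision; the `metrology` module does exactly
that and the acceptance script reports those measurements. Assembly uses a
voxel occupancy engine (z-column parity rasterization at 0.2 mm, array
Booleans, marching-cubes remesh): union of all bodies, embossed depth
domes, subtraction of the CSW width-limiting half-space, subtraction of the
bone dilated by one voxel (the negative cortical shape plus the seating
clearance a printed guide needs), cylindrical corner-gap clearances (Ø8 mm
default) along each junction line, and the Ø2.1 mm fixation bores. The
result is watertight by construction.

Open parameters the source design leaves free, fixed here once: pin tilt
15° from the approach at alternating, automatically separated azimuths
(minimum pairwise axis angle 5°); 2 pins per guiding segment, capped at 6;
clip spheres Ø10 mm with 0.25 mm pinch clearance per side; corner gap
radius 4 mm; depth marks every 10 mm; the 15 mm guiding offset is measured
along the (tilted) cut surface; fixation bosses carry Ø12 mm anchor
spheres.

One stated goal was relaxed deliberately: a keep-out of the tumor *dilated
by the full margin* cannot be honored by the main body — a Ø16 mm tube
centered on a trajectory ~12 mm from the silhouette necessarily enters a
10 mm dilation of a surface-bulging tumor. The enforced invariants are
instead: the guide never intersects the tumor itself (clearance reported),
and fixation axes stay outside tumor + margin and all configured keep-out
boxes.

## Validation

- *Margins*: ≥10⁴ samples per surface plus the exact vertex minimum,
  cross-checked against an O(V·F) oracle in the tests.
- *Virtual cut*: bone voxelized at 0.4 mm, kerf slabs (cut planes thickened
  to the 2 mm blade, clipped by neighbor planes) removed, connected
  components split into piece and remnant (sub-13 mm³ slivers along the
  kerf walls are discarded as debris). Breach is evaluated
  analytically (tumor vertices inside any kerf slab), extraction
  kinematically (voxel sweep of the piece along the approach with a 0.2%
  overlap tolerance for grid aliasing).
- *Conformity*: signed distances over the contact region (guide faces
  within 2 voxels of bone); negative = penetration. Expected band with the
  one-voxel seating clearance: ≈ [0, 0.5] mm.
- *Printability*: thin walls by morphological opening at min_wall/2
  (erosion/dilation via distance transforms), bore diameters from the
  complement clearance along each pin axis, max inscribed diameter from
  the interior distance transform.
- *Stability heuristic*: number/spread of distinct contact patches — a
  proxy only; no forces are computed.

## Problem sizes and determinism

Default problem sizes are the study conditions: phantom domain
155 × 70 × 155 mm at 1 mm CT / 1 × 1 × 1.5 mm MR spacing (~1.7M voxels),
bone meshes ~110k faces at 1 mm sampling, guide union at 0.2 mm. Tests that
double-run the full chain use a 0.35 mm union pitch — the determinism
property being checked is pitch-independent — and the decimation fixture
oversamples the bone at 0.8 mm before midpoint subdivision to >2M faces.
Every stochastic step derives from explicit seeds (phantom jitter, noise,
deformation field, metric sampling, surface sampling), so a fixed seed
reproduces byte-identical artifacts, which the manifest hashes assert.

## What the phantoms do not show

Passing on phantoms demonstrates the contracts (margin guarantee,
conformity, dimensional fidelity, recovery of known deformations), not
clinical performance: real bone has cortical/trabecular structure, MR
bias fields and resolution anisotropy beyond the model here; real pelvic
anatomy has soft-tissue corridors and noble structures the keep-out boxes
only caricature; watershed initialization on real data may need manual
correction; and guide strength, sterilization and intraoperative handling
are entirely out of scope.
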