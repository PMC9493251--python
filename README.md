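# oncocut

A digital chain for designing **patient-specific surgical cutting guides
(SCGs)** for pelvic bone tumor resection, built as a reproducible, fully
testable Python pipeline. It covers every stage from multimodal imaging to a
printable guide:

1. **Phantoms** — seeded synthetic hemipelvis-like bones with implantable
   tumors in the four Enneking resection zones (I iliac crest, II
   acetabulum, III ischium, I+IV sacroiliac), plus matching pseudo-CT and
   deformed pseudo-MR volumes with known ground truth. Everything downstream
   is testable without any data download.
2. **Volumes** — NRRD/NIfTI I/O, multi-resolution B-spline registration of
   MR to CT under Mattes mutual information, marker-based watershed
   segmentation on the gradient magnitude, and marching-cubes surface
   extraction in world millimetres.
3. **Mesh processing** — quadric edge-collapse decimation (exact face-count
   targets, locked boundaries, topology-preserving link condition) and
   exact vertex-to-surface Hausdorff distances.
4. **Planning** — the geometrical definition of the resection: a 3-point
   approach plane, the tumor's orthographic silhouette expanded by the
   oncologic margin *m* plus blade kerf *b* (total offset *m + b* = 10 + 2
   mm by default), a 1–4 segment resection polyline tangent to the expanded
   silhouette, and cut surfaces extruded with a 5° draft so the resected
   piece tapers like a cork. A 3D validation loop pushes segments outward
   until min ‖x_tumor − x_cut‖ ≥ m holds on every surface.
5. **Guide generation** — main body as a Ø16 mm circular sweep along the
   bone∩cut-surface trajectory, Ø20 mm spherical anchors at its nodes, a
   15 mm high / 7 mm thick elevated open-border guiding flange flush with
   the cut plane, local contact-surface widening (5 mm bone-conformal
   patch), an optional deformable clip for thin bone edges, drilled K-wire
   bosses (Ø6 outer / Ø2.1 bore, non-parallel axes), and finishing: Boolean
   union, negative cortical bone shape, corner-gap clearances and depth
   marks. Booleans run on a voxel occupancy engine (0.2 mm) and the result
   is a watertight binary STL.
6. **Validation** — achieved 3D margins, signed-distance bone conformity
   over the contact region, a virtual cut (kerf removal, piece/remnant
   split, tumor-breach and extraction tests), fixation-axis geometry and an
   SLS printability screen.

## Worked example

```bash
oncocut run --case zone_II_acetabulum --seed 1 --out out_zone2
```

runs the whole chain on the acetabular preset and prints the stage report:

```
{
  "stages": [
    {"name": "phantom",     "status": "ok", "seconds": 1.7},
    {"name": "inputs",      "status": "ok", "seconds": 0.0},
    {"name": "meshproc",    "status": "ok", "seconds": 0.7},
    {"name": "planning",    "status": "ok", "seconds": 9.3},
    {"name": "scg_builder", "status": "ok", "seconds": 46.4},
    {"name": "validation",  "status": "ok", "seconds": 16.9}
  ],
  "passed": true
}
```

`out_zone2/design_report.json` then holds the quantitative QC, e.g. (seed 1):

- `achieved_margin`: `{0: 10.16, 1: 10.35, 2: 10.43}` mm — the minimum
  tumor-to-cut distance per surface, all above the 10 mm oncologic margin
  (the planner auto-expanded each segment by 1.5 mm to pay for the margin
  the draft tilt consumes at depth);
- `tumor_breach: false` — the simulated blade kerf never touches the tumor;
- `piece_extractable: true` — the resected piece sweeps out along the
  approach without colliding with the remaining bone;
- `conformity`: min/mean/max signed distance of the guide's contact region
  to the bone ≈ 0.05 / 0.17 / 0.45 mm (no penetration, sub-mm seating gap);
- `min_pairwise_axis_angle: 11.9°` — no two K-wire axes are parallel.

`out_zone2/guide.stl` is the printable guide; `manifest.json` lists SHA-256
hashes of every artifact — rerunning with the same seed reproduces them
byte-for-byte.

The same stages are available as library calls (`oncocut.pipeline.plan_case`,
`oncocut.pipeline.build_guide`, `oncocut.validation.build_report`) and as
the `oncocut phantom / segment / plan / build / validate / run` subcommands.

## Scope

SLS print-process simulation, guide strength (FEA), sterilization and
surgeon-ergonomics scoring are out of scope; see `docs/methods.md` for the
model, parameter and limitation details.
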