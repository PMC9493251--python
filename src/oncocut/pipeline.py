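"""End-to-end orchestration: phantom -> (volumes) -> mesh QC -> planning ->
guide build -> validation, from a single config.

The default mode starts from meshes (phantom or user STL); the volumes mode
runs the full image chain (pseudo-CT/MR synthesis, deformable registration,
watershed segmentation, surface extraction) before planning. Every stage is
timed and all artifacts are written with a SHA-256 manifest so a fixed seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import trimesh
import yaml

from . import meshproc, phantom, planning, scg_builder, validation, volumes
from ._dist import closest_point_on_triangles

__all__ = ["RunConfig", "RunReport", "plan_case", "build_guide", "run",
           "load_config"]

_CONFIG_KEYS = {
    "case", "seed", "out_dir", "mode", "bone_path", "tumor_path",
    "oncologic_margin", "blade_thickness", "draft_angle", "n_segments",
    "extrusion_depth", "segment_margins", "polyline", "plane_points",
    "target_faces",
    "guide", "keep_out", "phantom", "registration",
}


@dataclass
class RunConfig:
    case: str = "zone_II_acetabulum"
    seed: int = 1
    out_dir: str = "oncocut_out"
    mode: str = "mesh"  # "mesh" skips the volumes stage; "volumes" runs it
    bone_path: str | None = None
    tumor_path: str | None = None
    oncologic_margin: float = planning.DEFAULT_MARGIN
    blade_thickness: float = planning.DEFAULT_BLADE
    draft_angle: float = planning.DEFAULT_DRAFT
    n_segments: int | None = None
    extrusion_depth: float | None = None
    segment_margins: dict = dc_field(default_factory=dict)
    polyline: list | None = None
    plane_points: list | None = None
    target_faces: int = 100_000
    guide: dict = dc_field(default_factory=dict)
    keep_out: list = dc_field(default_factory=list)
    phantom: dict = dc_field(default_factory=dict)
    registration: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("mesh", "volumes"):
            raise ValueError("mode must be 'mesh' or 'volumes'")
        if self.case is not None and self.case not in phantom.CASE_IDS:
            raise ValueError(f"unknown case {self.case!r}")
        self.segment_margins = {int(k): float(v)
                                for k, v in (self.segment_margins or {}).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    stages: list
    design_report: dict | None
    manifest: dict
    seed: int
    total_seconds: float

    def to_dict(self):
        return asdict(self)


def plan_case(case: phantom.PhantomCase, config: RunConfig | None = None,
              bone: trimesh.Trimesh | None = None,
              tumor: trimesh.Trimesh | None = None):
    """Run the geometrical definition for a phantom case: approach plane,
    silhouette + margin offset, fitted polyline, extrusion and 3D margin
    validation. Returns (plan, plan_report)."""
    config = config or RunConfig(case=case.case_id, seed=case.seed)
    bone = bone if bone is not None else case.bone
    tumor = tumor if tumor is not None else case.tumor
    if config.plane_points is not None:
        pts = [np.asarray(p, float) for p in config.plane_points]
    else:
        pts = case.plane_points()
    plane = planning.plane_from_points(*pts)
    bone_uv = plane.to_2d(bone.vertices)
    tumor_uv_c = plane.to_2d(tumor.vertices).mean(axis=0)
    if config.polyline is not None:
        poly = np.asarray(config.polyline, dtype=float)
    else:
        sil = planning.silhouette(tumor, plane)
        off = planning.offset_margin(
            sil, config.oncologic_margin + config.blade_thickness)
        d = tumor_uv_c - bone_uv.mean(axis=0)
        d /= np.linalg.norm(d)
        n_seg = config.n_segments or case.n_segments
        poly = planning.fit_polyline(off, n_seg, d, bone_uv)
    plan = planning.ResectionPlan(
        plane=plane, oncologic_margin=config.oncologic_margin,
        blade_thickness=config.blade_thickness,
        draft_angle=config.draft_angle, polyline=poly,
        extrusion_depth=config.extrusion_depth,
        segment_margins=config.segment_margins)
    report = planning.validate_plan(
        plan, tumor, bone=bone, tumor_uv_centroid=tumor_uv_c)
    return plan, report


def build_guide(case: phantom.PhantomCase, plan: planning.ResectionPlan,
                config: RunConfig | None = None,
                bone: trimesh.Trimesh | None = None,
                tumor: trimesh.Trimesh | None = None) -> scg_builder.SCGModel:
    """Five-step guide generation for a validated plan."""
    config = config or RunConfig(case=case.case_id, seed=case.seed)
    bone = bone if bone is not None else case.bone
    tumor = tumor if tumor is not None else case.tumor
    params = scg_builder.GuideParams(**config.guide)
    chains = scg_builder.intersection_curve(bone, plan.surfaces, case.approach)
    traj = scg_builder.make_trajectory(
        chains, plan.surfaces, tumor=tumor,
        anchor_radius=params.anchor_diameter / 2.0)
    bodies = {
        "main_body": [scg_builder.main_body(traj, params.sweep_diameter)],
        "anchors": scg_builder.anchors(traj, params.anchor_diameter),
        "guiding": scg_builder.guiding_feature(
            plan.surfaces, traj, case.approach,
            params.guiding_height, params.guiding_thickness),
    }
    # positioning: local contact-surface widening on the longest span
    span = max((s for s in traj.spans if not s["is_bridge"]),
               key=lambda s: len(s["points"]))
    surf = plan.surfaces[span["surface_index"]]
    mid = span["points"][len(span["points"]) // 2]
    _, cp, _ = closest_point_on_triangles(
        (mid + 18.0 * surf.plane_normal)[None, :],
        np.ascontiguousarray(bone.triangles))
    csw_limits = []
    try:
        csw = scg_builder.contact_surface_widening(
            bone, cp[0], params.csw_thickness, params.csw_max_width,
            limit_surface=surf, patch_radius=params.csw_patch_radius,
            tumor=tumor, margin=plan.oncologic_margin)
        bodies["csw"] = [csw]
        csw_limits.append((surf, params.csw_max_width))
    except ValueError:
        pass  # CSW region infeasible here; the clip / pins still position
    if case.clip_point is not None:
        try:
            clip_solids, _ = scg_builder.deformable_clip(
                bone, case.clip_point, case.approach,
                params.clip_bridge_thickness, params.clip_sphere_diameter,
                params.clip_fit_clearance, params.clip_max_edge_thickness)
            bodies["clip"] = clip_solids
        except ValueError:
            pass
    fix_solids, axes = scg_builder.fixation_features(
        plan.surfaces, traj, case.approach, params, tumor=tumor,
        margin=plan.oncologic_margin, keep_out=config.keep_out)
    bodies["fixation"] = fix_solids
    return scg_builder.finish(
        bodies, bone, plan.surfaces, traj, case.approach, params,
        pin_axes=axes, csw_limits=csw_limits)


def _volumes_stage(case: phantom.PhantomCase, config: RunConfig, out: Path,
                   artifacts: dict):
    """Paper-style image chain: synthesize CT/MR, register, segment both
    modalities, map the tumor into the CT frame, extract surfaces."""
    ct = phantom.synth_ct(case)
    mr, _gt = phantom.synth_mr(case)
    reg_opts = dict(config.registration)
    tx = volumes.register(ct, mr, **reg_opts)
    ct_markers = volumes.auto_markers(ct, volumes.BONE)
    ct_labels = volumes.segment_watershed(ct, ct_markers)
    mr_markers = volumes.auto_markers(mr, volumes.TUMOR)
    mr_labels = volumes.segment_watershed(mr, mr_markers)
    tumor_ct_frame = volumes.apply_transform(mr_labels, tx)
    bone_mesh = volumes.extract_surface(ct_labels, volumes.BONE, smooth_iters=3)
    tumor_mesh = volumes.extract_surface(tumor_ct_frame, volumes.TUMOR,
                                         smooth_iters=3)
    volumes.write_volume(ct, out / "ct.nrrd")
    volumes.write_volume(mr, out / "mr.nrrd")
    artifacts["ct.nrrd"] = out / "ct.nrrd"
    artifacts["mr.nrrd"] = out / "mr.nrrd"
    return bone_mesh, tumor_mesh


def run(config: RunConfig) -> RunReport:
    """Execute the digital chain per config; halts with the failing stage
    named. Deterministic for a fixed seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []
    artifacts: dict = {}
    t_all = time.perf_counter()
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:
            stages.append({"name": name, "status": "failed",
                           "seconds": time.perf_counter() - t0,
                           "error": str(e)})
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        stages.append({"name": name, "status": "ok",
                       "seconds": time.perf_counter() - t0})

    def s_phantom():
        params = phantom.PhantomParams(**config.phantom)
        state["case"] = phantom.make_case(config.case, config.seed, params)

    def s_inputs():
        case = state["case"]
        if config.bone_path:
            state["bone"] = meshproc.load_mesh(config.bone_path)
            state["tumor"] = meshproc.load_mesh(config.tumor_path)
        elif config.mode == "volumes":
            state["bone"], state["tumor"] = _volumes_stage(
                case, config, out, artifacts)
        else:
            state["bone"] = case.bone
            state["tumor"] = case.tumor

    def s_meshproc():
        bone = state["bone"]
        if len(bone.faces) > config.target_faces:
            bone = meshproc.decimate(bone, config.target_faces)
            state["bone"] = bone
        state["bone_qc"] = meshproc.qc_mesh(bone, check_self_intersections=False)
        meshproc.save_mesh(bone, out / "bone.stl")
        meshproc.save_mesh(state["tumor"], out / "tumor.stl")
        artifacts["bone.stl"] = out / "bone.stl"
        artifacts["tumor.stl"] = out / "tumor.stl"

    def s_planning():
        plan, plan_report = plan_case(
            state["case"], config, bone=state["bone"], tumor=state["tumor"])
        state["plan"] = plan
        state["plan_report"] = plan_report
        payload = {
            "polyline": plan.polyline.tolist(),
            "oncologic_margin": plan.oncologic_margin,
            "blade_thickness": plan.blade_thickness,
            "total_offset": plan.total_offset,
            "draft_angle": plan.draft_angle,
            "validation": plan_report,
        }
        (out / "plan.json").write_text(json.dumps(payload, indent=2, sort_keys=True, default=_np_default))
        artifacts["plan.json"] = out / "plan.json"

    def s_build():
        scg = build_guide(state["case"], state["plan"], config,
                          bone=state["bone"], tumor=state["tumor"])
        state["scg"] = scg
        scg_builder.export_guide(scg, out / "guide.stl")
        artifacts["guide.stl"] = out / "guide.stl"
        sidecar = {
            "pin_axes": [[p.tolist(), a.tolist()] for p, a in scg.pin_axes],
            "bodies": {k: len(v) for k, v in scg.bodies.items()},
            "metadata": scg.metadata,
        }
        (out / "guide_features.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True, default=_np_default))
        artifacts["guide_features.json"] = out / "guide_features.json"

    def s_validate():
        _, _, cut = validation.simulate_cut(
            state["bone"], state["plan"].surfaces,
            blade_thickness=state["plan"].blade_thickness,
            tumor=state["tumor"], approach=state["case"].approach)
        report = validation.build_report(
            state["scg"], state["bone"], state["tumor"], state["plan"],
            cut_report=cut)
        state["design_report"] = report
        (out / "design_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True, default=_np_default))
        (out / "design_report.md").write_text(report.to_markdown())
        artifacts["design_report.json"] = out / "design_report.json"
        artifacts["design_report.md"] = out / "design_report.md"

    stage("phantom", s_phantom)
    stage("inputs", s_inputs)
    stage("meshproc", s_meshproc)
    stage("planning", s_planning)
    stage("scg_builder", s_build)
    stage("validation", s_validate)

    manifest = {name: _sha256(path) for name, path in sorted(artifacts.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report = RunReport(
        stages=stages,
        design_report=state["design_report"].to_dict(),
        manifest=manifest,
        seed=config.seed,
        total_seconds=time.perf_counter() - t_all,
    )
    (out / "run_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=_np_default))
    return report


def _np_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
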