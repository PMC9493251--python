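"""Quantitative QC of a planned resection and its cutting guide: achieved
margins, bone conformity, virtual cut simulation, fixation-axis geometry and
printability.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import trimesh
from scipy import ndimage

from ._dist import min_dist_to_triangles, points_in_mesh
from ._voxel import VoxelGrid, voxelize, occupancy_to_mesh
from .meshproc import MeshQCReport, qc_mesh, surface_distance
from .scg_builder import SCGModel, min_pairwise_angle

__all__ = [
    "DesignReport",
    "achieved_margin",
    "simulate_cut",
    "conformity",
    "printability",
    "stability_patches",
    "build_report",
]


@dataclass
class DesignReport:
    achieved_margin: dict  # surface index -> mm
    required_margin: dict
    conformity: dict  # {min, max, mean} signed mm
    min_pairwise_axis_angle: float
    tumor_breach: bool
    piece_extractable: bool
    printability: dict
    qc: dict
    guide_tumor_clearance: float | None = None
    contact_patches: dict = dc_field(default_factory=dict)

    @property
    def passed(self) -> bool:
        margins_ok = all(
            self.achieved_margin[k] >= self.required_margin[k] - 1e-9
            for k in self.achieved_margin)
        return (margins_ok and not self.tumor_breach
                and self.qc.get("watertight", False)
                and self.min_pairwise_axis_angle > 0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passed"] = self.passed
        return d

    def to_markdown(self) -> str:
        lines = ["# Design report", ""]
        lines.append("| cut surface | required margin (mm) | achieved (mm) |")
        lines.append("|---|---|---|")
        for k in sorted(self.achieved_margin):
            lines.append(f"| {k} | {self.required_margin[k]:.1f} | "
                         f"{self.achieved_margin[k]:.2f} |")
        c = self.conformity
        lines += [
            "",
            f"- Conformity (signed distance to bone over the contact region): "
            f"min {c['min']:.3f} / mean {c['mean']:.3f} / max {c['max']:.3f} mm",
            f"- Minimum pairwise fixation-axis angle: "
            f"{self.min_pairwise_axis_angle:.1f} deg",
            f"- Tumor breached by a cutting plane: "
            f"{'YES' if self.tumor_breach else 'no'}",
            f"- Resected piece extractable along the approach: "
            f"{'yes' if self.piece_extractable else 'NO'}",
            f"- Printability: {self.printability}",
            f"- Guide watertight: {self.qc.get('watertight')}",
            f"- Overall: {'PASS' if self.passed else 'FAIL'}",
        ]
        return "\n".join(lines)


def _surface_min_distance(surf, tumor: trimesh.Trimesh, n_samples: int,
                          rng_seed: int = 0) -> float:
    """Min distance between a cut surface and the tumor: dense surface
    sampling cross-checked with the exact tumor-vertex minimum."""
    tris = np.ascontiguousarray(surf.mesh.triangles, dtype=np.float64)
    d_vert = float(min_dist_to_triangles(
        np.ascontiguousarray(tumor.vertices, dtype=np.float64), tris).min())
    samples = surf.sample(n=n_samples, rng=np.random.default_rng(rng_seed))
    d_samp = float(surface_distance(samples, tumor).min())
    return min(d_vert, d_samp)


def achieved_margin(tumor: trimesh.Trimesh, resection_surfaces: list,
                    n_samples: int = 10_000) -> dict:
    """Per-surface minimum 3D distance from the tumor to each cut surface."""
    return {
        i: _surface_min_distance(s, tumor, n_samples, rng_seed=13 + i)
        for i, s in enumerate(resection_surfaces)
    }


def _kerf_masks(grid: VoxelGrid, surfaces: list, blade: float) -> list:
    """Voxel mask of each blade kerf: slab around the cut plane, clipped to
    the active region by the adjacent planes."""
    xs, ys, zs = grid.world_grid()
    gvals = []
    for s in surfaces:
        p, n = s.plane_point, s.plane_normal
        gvals.append((xs - p[0]) * n[0] + (ys - p[1]) * n[1] + (zs - p[2]) * n[2])
    masks = []
    for i, s in enumerate(surfaces):
        m = np.abs(gvals[i]) <= blade / 2.0
        for j, o in enumerate(surfaces):
            if abs(o.segment_index - s.segment_index) == 1:
                m &= gvals[j] <= blade / 2.0
        masks.append(m)
    return masks


def simulate_cut(bone: trimesh.Trimesh, resection_surfaces: list,
                 blade_thickness: float = 2.0, tumor: trimesh.Trimesh | None = None,
                 approach: np.ndarray | None = None, pitch: float = 0.4,
                 sweep_distance: float = 40.0):
    """Virtual resection: remove the blade kerf from the bone, split it, and
    check that no cutting plane touches the tumor and that the piece sweeps
    out along the approach without colliding with the remaining bone.

    Returns ``(resected_piece, remaining_bone, report)`` where the meshes
    are reconstructed from the voxel split and the report carries
    ``breach``, ``extractable``, ``removed_volume`` and component info.
    """
    grid = VoxelGrid.empty(bone.bounds[0], bone.bounds[1], pitch, pad=3)
    bone_occ = voxelize(bone, grid.origin, grid.pitch, grid.shape)
    grid.occ = bone_occ.copy()
    kerfs = _kerf_masks(grid, resection_surfaces, blade_thickness)
    removed = np.zeros_like(bone_occ)
    for m in kerfs:
        removed |= m & bone_occ
    remaining = bone_occ & ~removed
    labels, n = ndimage.label(remaining)
    # drop sub-voxel debris slivers left along the kerf walls
    counts = np.bincount(labels.ravel())
    debris = np.flatnonzero(counts < 200)
    if len(debris):
        remaining &= ~np.isin(labels, debris)
        labels, n = ndimage.label(remaining)

    breach = False
    if tumor is not None:
        tv = np.asarray(tumor.vertices)
        for s in resection_surfaces:
            g = (tv - s.plane_point) @ s.plane_normal
            inside = np.abs(g) <= blade_thickness / 2.0
            for o in resection_surfaces:
                if abs(o.segment_index - s.segment_index) == 1:
                    inside &= (tv - o.plane_point) @ o.plane_normal <= blade_thickness / 2.0
            if inside.any():
                breach = True
        centroid = np.asarray(tumor.vertices).mean(axis=0)
    else:
        centroid = np.asarray(bone.vertices).mean(axis=0)

    ci = np.clip(((centroid - grid.origin) / pitch).round().astype(int),
                 0, np.array(grid.shape) - 1)
    piece_label = labels[tuple(ci)]
    if piece_label == 0:
        # centroid voxel not in remaining bone (e.g. exophytic tumor): use
        # the component nearest to the centroid
        occ_idx = np.argwhere(remaining)
        near = occ_idx[np.argmin(np.abs(occ_idx - ci).sum(axis=1))]
        piece_label = labels[tuple(near)]
    piece = labels == piece_label
    rest = remaining & ~piece
    through = bool(rest.any()) and n >= 2

    extractable = None
    if approach is not None and through:
        extractable = _sweep_clear(piece, rest, np.asarray(approach, float),
                                   pitch, sweep_distance)

    report = {
        "breach": bool(breach),
        "through_cut": through,
        "extractable": extractable,
        "removed_volume": float(removed.sum()) * pitch**3,
        "n_components": int(n),
        "piece_volume": float(piece.sum()) * pitch**3,
    }
    piece_mesh = occupancy_to_mesh(piece, grid.origin, pitch) if piece.any() else None
    rest_mesh = occupancy_to_mesh(rest, grid.origin, pitch) if rest.any() else None
    return piece_mesh, rest_mesh, report


def _sweep_clear(piece: np.ndarray, rest: np.ndarray, approach: np.ndarray,
                 pitch: float, distance: float, tol_fraction: float = 2e-3) -> bool:
    """Kinematic extraction test: translate the piece along the approach in
    voxel steps; it must never overlap the remaining bone."""
    approach = approach / np.linalg.norm(approach)
    n_piece = piece.sum()
    steps = np.arange(1.0, distance, pitch * 2.0)
    for t in steps:
        off = np.round(approach * t / pitch).astype(int)
        shifted = piece
        for ax, o in enumerate(off):
            if o != 0:
                shifted = np.roll(shifted, o, axis=ax)
                # zero-fill the wrap
                sl = [slice(None)] * 3
                sl[ax] = slice(0, o) if o > 0 else slice(o, None)
                shifted = shifted.copy()
                shifted[tuple(sl)] = False
        overlap = (shifted & rest).sum()
        if overlap > tol_fraction * n_piece:
            return False
    return True


def conformity(scg: SCGModel, bone: trimesh.Trimesh,
               n_samples: int = 5000) -> dict:
    """Signed distance statistics over the guide's bone-contact region
    (negative = penetration into bone)."""
    region = scg.contact_region
    if region is None or len(region.faces) == 0:
        raise ValueError("empty contact region")
    samples, _ = trimesh.sample.sample_surface(
        region, n_samples, seed=11)
    samples = np.ascontiguousarray(samples, dtype=np.float64)
    d = surface_distance(samples, bone)
    tris = np.ascontiguousarray(bone.triangles, dtype=np.float64)
    inside = points_in_mesh(samples, tris)
    signed = np.where(inside, -d, d)
    return {
        "min": float(signed.min()),
        "max": float(signed.max()),
        "mean": float(signed.mean()),
        "n_samples": int(n_samples),
    }


def printability(scg: SCGModel, min_wall: float = 1.0, min_hole: float = 1.0,
                 pitch: float = 0.4, thin_fraction_tol: float = 0.02) -> dict:
    """SLS printability screen on the voxelized solid.

    Thin walls are found by a morphological opening at radius min_wall/2
    (erosion/dilation through distance transforms); bore diameters are
    measured as twice the clearance of the complement along each pin axis.
    """
    solid = scg.solid
    grid = VoxelGrid.empty(solid.bounds[0], solid.bounds[1], pitch, pad=4)
    occ = voxelize(solid, grid.origin, grid.pitch, grid.shape)
    edt_in = ndimage.distance_transform_edt(occ) * pitch
    r = min_wall / 2.0
    eroded = edt_in > r
    dist_to_eroded = ndimage.distance_transform_edt(~eroded) * pitch
    opened = dist_to_eroded <= r
    thin = occ & ~opened
    thin_fraction = float(thin.sum()) / max(float(occ.sum()), 1.0)

    edt_out = ndimage.distance_transform_edt(~occ) * pitch
    hole_diams = []
    for base, axis in scg.pin_axes:
        ts = np.linspace(2.0, scg.params.fixation_length - 2.0, 15)
        pts = base[None, :] + ts[:, None] * axis[None, :]
        idx = np.clip(((pts - grid.origin) / pitch).round().astype(int),
                      0, np.array(grid.shape) - 1)
        vals = edt_out[idx[:, 0], idx[:, 1], idx[:, 2]]
        inside_bore = vals > 0
        if inside_bore.any():
            hole_diams.append(2.0 * float(np.median(vals[inside_bore])))
    measured_hole = min(hole_diams) if hole_diams else None
    return {
        "min_wall": float(min_wall),
        "min_hole": float(min_hole),
        "thin_fraction": thin_fraction,
        "wall_ok": thin_fraction <= thin_fraction_tol,
        "bore_diameter_nominal": float(scg.params.fixation_inner),
        "bore_diameter_measured": measured_hole,
        "hole_ok": float(scg.params.fixation_inner) >= min_hole,
        "max_inscribed_diameter": float(edt_in.max()) * 2.0,
    }


def stability_patches(scg: SCGModel, min_area: float = 30.0) -> dict:
    """Positioning-stability heuristic: number and spread of distinct
    bone-contact patches (guides spanning three or more cut planes seat on
    more, better-spread patches)."""
    parts = scg.contact_region.split(only_watertight=False)
    patches = [p for p in parts if p.area >= min_area]
    centers = np.array([p.triangles_center.mean(axis=0) for p in patches]) \
        if patches else np.zeros((0, 3))
    spread = 0.0
    noncollinear = False
    if len(centers) >= 2:
        spread = float(max(np.linalg.norm(a - b)
                           for i, a in enumerate(centers)
                           for b in centers[i + 1:]))
    if len(centers) >= 3:
        c = centers - centers.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        noncollinear = bool(s[1] > 1e-3 * max(s[0], 1e-9))
    return {
        "n_patches": len(patches),
        "spread": spread,
        "noncollinear": noncollinear,
    }


def build_report(scg: SCGModel, bone: trimesh.Trimesh, tumor: trimesh.Trimesh,
                 plan, cut_report: dict | None = None,
                 n_margin_samples: int = 10_000) -> DesignReport:
    """Assemble the full design report for a built guide."""
    margins = achieved_margin(tumor, plan.surfaces, n_samples=n_margin_samples)
    required = {i: plan.margin_for(i) for i in margins}
    conf = conformity(scg, bone)
    qc = qc_mesh(scg.solid, check_self_intersections=False)
    clearance = float(surface_distance(
        np.asarray(tumor.vertices), scg.solid).min())
    if cut_report is None:
        _, _, cut_report = simulate_cut(
            bone, plan.surfaces, blade_thickness=plan.blade_thickness,
            tumor=tumor)
    return DesignReport(
        achieved_margin=margins,
        required_margin=required,
        conformity=conf,
        min_pairwise_axis_angle=min_pairwise_angle(scg.pin_axes),
        tumor_breach=bool(cut_report["breach"]),
        piece_extractable=bool(cut_report.get("extractable")
                               if cut_report.get("extractable") is not None
                               else False),
        printability=printability(scg),
        qc=qc.to_dict(),
        guide_tumor_clearance=clearance,
        contact_patches=stability_patches(scg),
    )
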