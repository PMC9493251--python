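"""Surgical cutting guide (SCG) generation.

Five-step build, mirroring how pelvic cutting guides are designed in
practice: (1) main body -- a circular sweep along the bone/cut-surface
intersection trajectory, with spherical anchors at its nodes; (2) guiding
feature -- an elevated open-border flange whose inner face is flush with
the cut plane; (3) positioning features -- local contact-surface widening
(CSW) and an optional deformable clip pinching a thin bone edge; (4)
fixation features -- drilled K-wire bosses with non-parallel axes; (5)
finishing -- Boolean union, subtraction of the bone (negative cortical
shape), corner-gap clearances at plane junctions, bore holes and depth
marks. Booleans run on the voxel occupancy engine; individual bodies are
exact parametric meshes so printed dimensions can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh

from ._dist import min_dist_to_triangles, ray_mesh_hits, closest_point_on_triangles
from ._voxel import VoxelGrid
from .meshproc import qc_mesh

__all__ = [
    "GuideParams",
    "GuideTrajectory",
    "SCGModel",
    "intersection_curve",
    "make_trajectory",
    "main_body",
    "anchors",
    "guiding_feature",
    "contact_surface_widening",
    "deformable_clip",
    "fixation_features",
    "finish",
    "export_guide",
]


@dataclass
class GuideParams:
    """Every printed dimension of the guide (mm / degrees)."""

    sweep_diameter: float = 16.0
    anchor_diameter: float = 20.0
    guiding_height: float = 15.0
    guiding_thickness: float = 7.0
    csw_thickness: float = 5.0
    csw_max_width: float = 30.0
    csw_patch_radius: float = 12.0
    clip_bridge_thickness: float = 5.0
    clip_sphere_diameter: float = 10.0
    clip_fit_clearance: float = 0.25
    clip_max_edge_thickness: float = 12.0
    fixation_outer: float = 6.0
    fixation_inner: float = 2.1
    fixation_length: float = 18.0
    fixation_anchor_diameter: float = 12.0
    kwire_diameter: float = 2.0
    pin_tilt: float = 15.0
    min_pairwise_axis_angle: float = 5.0
    pins_per_segment: int = 2
    max_pins: int = 6
    corner_gap_radius: float = 4.0
    depth_mark_spacing: float = 10.0
    voxel_pitch: float = 0.2

    def __post_init__(self):
        if self.fixation_inner <= self.kwire_diameter:
            raise ValueError("fixation bore must clear the K-wire diameter")
        for name in ("sweep_diameter", "anchor_diameter", "guiding_height",
                     "guiding_thickness", "csw_thickness", "fixation_outer",
                     "fixation_inner", "voxel_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GuideTrajectory:
    """Node/span decomposition of the bone-surface cutting trajectory.

    Nodes are cut extremities and crossings of resection-plane junctions;
    spans are smooth curves on bone (is_bridge spans are straight jumps
    across bone holes such as foramina)."""

    nodes: np.ndarray  # (m, 3)
    spans: list  # dicts: points (k,3), surface_index, is_bridge

    def polyline(self) -> np.ndarray:
        pts = [self.spans[0]["points"]]
        for sp in self.spans[1:]:
            pts.append(sp["points"][1:])
        return np.vstack(pts)

    @property
    def length(self) -> float:
        p = self.polyline()
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


@dataclass
class SCGModel:
    solid: trimesh.Trimesh
    bodies: dict
    pin_axes: list  # (point, unit direction)
    contact_region: trimesh.Trimesh
    params: GuideParams
    metadata: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# trajectory


def _chain_segments(segments: np.ndarray, tol: float = 1e-5):
    """Order mesh_plane segments into polyline chains (graph walk over
    coincident endpoints)."""
    if len(segments) == 0:
        return []
    key = lambda p: tuple(np.round(p / tol).astype(np.int64))
    adj: dict = {}
    for si, seg in enumerate(segments):
        for e in range(2):
            adj.setdefault(key(seg[e]), []).append((si, e))
    used = np.zeros(len(segments), dtype=bool)
    chains = []
    for start in range(len(segments)):
        if used[start]:
            continue
        # walk both directions from this segment
        chain = [segments[start, 0], segments[start, 1]]
        used[start] = True
        for direction in (1, 0):
            while True:
                k = key(chain[-1] if direction == 1 else chain[0])
                nxt = [(si, e) for si, e in adj.get(k, []) if not used[si]]
                if not nxt:
                    break
                si, e = nxt[0]
                used[si] = True
                new_pt = segments[si, 1 - e]
                if direction == 1:
                    chain.append(new_pt)
                else:
                    chain.insert(0, new_pt)
        chains.append(np.asarray(chain))
    return chains


def intersection_curve(bone: trimesh.Trimesh, resection_surfaces: list,
                       approach: np.ndarray, facing_cos: float = 0.15,
                       junction_tol: float = 0.05) -> list:
    """Ordered bone/cut-surface intersection chains per surface.

    Only the approach-facing side of the bone is kept (the guide rides the
    exposed surface); each surface's curve is clipped to its active region
    (the side of the adjacent planes bounding the piece), and chains are
    split naturally where bone holes (foramina) interrupt the curve.
    Returns a list (one entry per surface) of dicts with ordered ``chains``
    and junction crossing estimates.
    """
    approach = np.asarray(approach, dtype=float)
    approach /= np.linalg.norm(approach)
    face_normals = bone.face_normals
    results = []
    any_hit = False
    for idx, surf in enumerate(resection_surfaces):
        segs, face_idx = trimesh.intersections.mesh_plane(
            bone, surf.plane_normal, surf.plane_point, return_faces=True)
        if len(segs):
            any_hit = True
        keep = face_normals[face_idx] @ approach > facing_cos
        segs = segs[keep]
        # clip to the active region: on the piece side of the adjacent planes
        neighbors = []
        for other in resection_surfaces:
            if other is surf:
                continue
            if abs(other.segment_index - surf.segment_index) == 1:
                neighbors.append(other)
        for nb in neighbors:
            segs = _clip_segments_halfspace(segs, nb.plane_point, nb.plane_normal,
                                            junction_tol)
        chains = _chain_segments(segs) if len(segs) else []
        # orient and sort chains along the segment direction
        a3 = surf.mesh.vertices[0]
        b3 = surf.mesh.vertices[1]
        t3 = (b3 - a3) / np.linalg.norm(b3 - a3)
        oriented = []
        for ch in chains:
            t = (ch - a3) @ t3
            if t[-1] < t[0]:
                ch = ch[::-1]
                t = t[::-1]
            if len(ch) >= 2:
                oriented.append((float(t.min()), float(t.max()), ch))
        oriented.sort(key=lambda c: c[0])
        # keep the approach-facing envelope: drop chains buried under a
        # shallower chain covering the same lateral interval
        kept = []
        for t0, t1, ch in sorted(oriented, key=lambda c: -np.mean(c[2] @ approach)):
            overlap = 0.0
            for u0, u1, _ in kept:
                overlap = max(overlap, min(t1, u1) - max(t0, u0))
            if overlap < 0.5 * (t1 - t0):
                kept.append((t0, t1, ch))
        kept.sort(key=lambda c: c[0])
        results.append({
            "surface_index": idx,
            "chains": [ch for _, _, ch in kept],
            "t_dir": t3,
            "t_origin": a3,
        })
    if not any_hit:
        raise ValueError("resection surfaces do not intersect the bone")
    return results


def _clip_segments_halfspace(segs, point, normal, tol):
    """Keep segment parts with (x - point) . normal <= tol (piece side of a
    neighboring cut plane), splitting segments that straddle the plane."""
    if len(segs) == 0:
        return segs
    g = (segs - point) @ normal
    out = []
    for seg, gg in zip(segs, g):
        if gg[0] <= tol and gg[1] <= tol:
            out.append(seg)
        elif gg[0] > tol and gg[1] > tol:
            continue
        else:
            t = (tol - gg[0]) / (gg[1] - gg[0])
            cross = seg[0] + t * (seg[1] - seg[0])
            if gg[0] <= tol:
                out.append(np.stack([seg[0], cross]))
            else:
                out.append(np.stack([cross, seg[1]]))
    return np.asarray(out) if out else np.zeros((0, 2, 3))


def _smooth_chain(points: np.ndarray, max_dev: float = 0.5) -> np.ndarray:
    """Least-squares smoothing spline through a chain, bounded deviation."""
    from scipy import interpolate

    if len(points) < 4:
        return points.copy()
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(d)])
    total = u[-1]
    if total <= 0:
        return points.copy()
    u /= total
    s = len(points) * 0.01
    while True:
        tck, _ = interpolate.splprep(points.T, u=u, s=s, k=3)
        uu = np.linspace(0, 1, max(len(points), 32))
        fitted = np.asarray(interpolate.splev(uu, tck)).T
        dmax = _polyline_deviation(fitted, points)
        if dmax < max_dev or s < 1e-6:
            return fitted
        s *= 0.25


def _polyline_deviation(fitted: np.ndarray, raw: np.ndarray) -> float:
    """Max distance from fitted samples to the raw polyline."""
    best = np.full(len(fitted), np.inf)
    a = raw[:-1]
    b = raw[1:]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    denom[denom == 0] = 1.0
    for i, p in enumerate(fitted):
        t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0, 1)
        proj = a + t[:, None] * ab
        best[i] = np.linalg.norm(proj - p, axis=1).min()
    return float(best.max())


def make_trajectory(chain_data: list, surfaces: list,
                    tumor: trimesh.Trimesh | None = None,
                    extremity_overshoot: float = 20.0,
                    anchor_radius: float = 10.0, max_dev: float = 0.5,
                    min_fragment: float = 3.0) -> GuideTrajectory:
    """Assemble the guide trajectory: smooth spline spans between nodes
    (nodes = cut extremities + resection-plane junction crossings), with
    straight bridge spans across interrupting bone holes.

    The cut extremities bound the working region: when a tumor is given,
    each surface's chains are clipped to the tumor's extent along the cut
    direction plus ``extremity_overshoot`` (through-cuts extend across the
    whole bone, but the guide only spans the region the surgeon works in).
    Residual fragments shorter than ``min_fragment`` are dropped."""
    if not any(cd["chains"] for cd in chain_data):
        raise ValueError("no intersection chains")
    if tumor is not None:
        chain_data = _window_chains(chain_data, tumor, extremity_overshoot,
                                    min_fragment)
        if not any(cd["chains"] for cd in chain_data):
            raise ValueError("no intersection chains near the tumor window")
    spans = []
    nodes = []
    last_end = None
    for cd in chain_data:
        surf = surfaces[cd["surface_index"]]
        for ci, ch in enumerate(cd["chains"]):
            smoothed = _smooth_chain(ch, max_dev=max_dev)
            # project the span back onto its (planar) cut surface: nodes must
            # lie on the resection surface exactly
            n3 = surf.plane_normal
            smoothed = smoothed - np.outer(
                (smoothed - surf.plane_point) @ n3, n3)
            if last_end is not None:
                gap = np.linalg.norm(smoothed[0] - last_end)
                if gap > 1e-6:
                    is_junction = ci == 0  # first chain of a new surface
                    if is_junction and gap < 2 * anchor_radius:
                        # junction crossing on bone: weld at the midpoint
                        mid = 0.5 * (smoothed[0] + last_end)
                        spans[-1]["points"][-1] = mid
                        smoothed[0] = mid
                        nodes.append(mid)
                    elif is_junction and surf.junction_start is not None:
                        # chains part ways before the junction: bridge across
                        # it and drop the node where the bridge crosses the
                        # junction line
                        jp, jd = surf.junction_start
                        A, B = last_end, smoothed[0]
                        ab = B - A
                        M = np.eye(3) - np.outer(jd, jd)
                        denom = ab @ M @ ab
                        t = float(np.clip((jp - A) @ M @ ab / denom, 0.0, 1.0)) \
                            if denom > 1e-12 else 0.5
                        node = A + t * ab
                        nodes.append(node)
                        for a, b in ((A, node), (node, B)):
                            if np.linalg.norm(b - a) > 1e-6:
                                spans.append({
                                    "points": np.stack([a, b]),
                                    "surface_index": cd["surface_index"],
                                    "is_bridge": True,
                                })
                    else:
                        # bridge straight across the hole / junction gap
                        spans.append({
                            "points": np.stack([last_end, smoothed[0]]),
                            "surface_index": cd["surface_index"],
                            "is_bridge": True,
                        })
            else:
                nodes.append(smoothed[0])  # first extremity
            spans.append({
                "points": smoothed,
                "surface_index": cd["surface_index"],
                "is_bridge": False,
            })
            last_end = smoothed[-1]
    nodes.append(last_end)  # last extremity
    total = sum(
        float(np.linalg.norm(np.diff(sp["points"], axis=0), axis=1).sum())
        for sp in spans if not sp["is_bridge"])
    if total < anchor_radius:
        raise ValueError(
            f"trajectory on bone is only {total:.1f} mm, shorter than the "
            f"anchor radius")
    return GuideTrajectory(nodes=np.asarray(nodes), spans=spans)


def _window_chains(chain_data: list, tumor: trimesh.Trimesh,
                   overshoot: float, min_fragment: float) -> list:
    out = []
    tv = np.asarray(tumor.vertices)
    for cd in chain_data:
        t_dir = cd["t_dir"]
        t_origin = cd["t_origin"]
        tt = (tv - t_origin) @ t_dir
        lo, hi = float(tt.min()) - overshoot, float(tt.max()) + overshoot
        chains = []
        for ch in cd["chains"]:
            t = (ch - t_origin) @ t_dir
            keep = (t >= lo) & (t <= hi)
            if not keep.any():
                continue
            # trim to the window (chains are ordered by increasing t)
            idx = np.flatnonzero(keep)
            ch = ch[idx[0]:idx[-1] + 1]
            if len(ch) < 2:
                continue
            if np.linalg.norm(np.diff(ch, axis=0), axis=1).sum() < min_fragment:
                continue
            chains.append(ch)
        out.append({**cd, "chains": chains})
    return out


# ---------------------------------------------------------------------------
# solid bodies (parametric, watertight by construction)


def _parallel_frames(path: np.ndarray):
    tangents = np.gradient(path, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    normals = np.empty_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tangents[0], ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = np.cross(tangents[0], ref)
    n /= np.linalg.norm(n)
    for i, t in enumerate(tangents):
        n = n - np.dot(n, t) * t
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            n = np.cross(t, ref)
            nn = np.linalg.norm(n)
        n /= nn
        normals[i] = n
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def _sweep(path: np.ndarray, profile: np.ndarray) -> trimesh.Trimesh:
    """Sweep a closed 2D profile along a 3D path with parallel-transport
    frames; capped with triangle fans; watertight."""
    _, normals, binormals = _parallel_frames(path)
    k = len(profile)
    rings = (path[:, None, :]
             + profile[None, :, 0, None] * normals[:, None, :]
             + profile[None, :, 1, None] * binormals[:, None, :])
    nv = len(path) * k
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(len(path) - 1):
        for j in range(k):
            a = i * k + j
            b = i * k + (j + 1) % k
            c = (i + 1) * k + j
            d = (i + 1) * k + (j + 1) % k
            faces += [[a, b, d], [a, d, c]]
    # caps
    verts = np.vstack([verts, path[0], path[-1]])
    c0, c1 = nv, nv + 1
    for j in range(k):
        faces.append([c0, (j + 1) % k, j])
        base = (len(path) - 1) * k
        faces.append([c1, base + j, base + (j + 1) % k])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _circle_profile(radius: float, n: int = 64) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th)])


def _resample_path(path: np.ndarray, step: float) -> np.ndarray:
    d = np.linalg.norm(np.diff(path, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(d)])
    total = u[-1]
    n = max(int(np.ceil(total / step)), 2)
    uu = np.linspace(0, total, n + 1)
    out = np.empty((n + 1, 3))
    for c in range(3):
        out[:, c] = np.interp(uu, u, path[:, c])
    return out


def main_body(trajectory: GuideTrajectory, sweep_diameter: float = 16.0,
              step: float = 1.0) -> trimesh.Trimesh:
    """Solid circular sweep of the given diameter along the trajectory."""
    path = _resample_path(trajectory.polyline(), step)
    return _sweep(path, _circle_profile(sweep_diameter / 2.0))


def anchors(trajectory: GuideTrajectory, anchor_diameter: float = 20.0) -> list:
    """One sphere per node, linking the main-body segments."""
    out = []
    for node in trajectory.nodes:
        s = trimesh.creation.icosphere(subdivisions=3, radius=anchor_diameter / 2.0)
        s.apply_translation(node)
        out.append(s)
    return out


def _surface_up(surf, approach: np.ndarray) -> np.ndarray:
    """Unit direction 'upward along the resection surface' (toward approach,
    within the cut plane)."""
    n3 = surf.plane_normal
    u = approach - np.dot(approach, n3) * n3
    nn = np.linalg.norm(u)
    if nn < 1e-9:
        raise ValueError("approach is normal to the cut surface")
    return u / nn


def guiding_feature(surfaces: list, trajectory: GuideTrajectory,
                    approach: np.ndarray, guiding_height: float = 15.0,
                    guiding_thickness: float = 7.0) -> list:
    """Elevated open-border guiding flange per (non-bridge) span.

    The span curve is offset ``guiding_height`` upward along its cut
    surface; the strip between the two curves is the inner guiding face
    (flush with the cut plane) and is thickened ``guiding_thickness`` on
    the side opposite the resected piece."""
    bodies = []
    for sp in trajectory.spans:
        if sp["is_bridge"]:
            continue
        surf = surfaces[sp["surface_index"]]
        up = _surface_up(surf, approach)
        n3 = surf.plane_normal  # away from the piece
        lower = sp["points"]
        if len(lower) < 2:
            continue
        upper = lower + guiding_height * up
        k = len(lower)
        inner = np.vstack([lower, upper])  # 2k verts on the cut plane
        outer = inner + guiding_thickness * n3
        verts = np.vstack([inner, outer])
        L, U, Lo, Uo = (np.arange(k), np.arange(k) + k,
                        np.arange(k) + 2 * k, np.arange(k) + 3 * k)
        faces = []
        for i in range(k - 1):
            # inner face (normal toward the piece, i.e. -n3)
            faces += [[L[i], U[i], U[i + 1]], [L[i], U[i + 1], L[i + 1]]]
            # outer face
            faces += [[Lo[i], Uo[i + 1], Uo[i]], [Lo[i], Lo[i + 1], Uo[i + 1]]]
            # lower edge wall
            faces += [[L[i], Lo[i], Lo[i + 1]], [L[i], Lo[i + 1], L[i + 1]]]
            # upper edge wall
            faces += [[U[i], Uo[i + 1], Uo[i]], [U[i], U[i + 1], Uo[i + 1]]]
        # end walls
        faces += [[L[0], Uo[0], U[0]], [L[0], Lo[0], Uo[0]]]
        faces += [[L[-1], U[-1], Uo[-1]], [L[-1], Uo[-1], Lo[-1]]]
        body = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                               process=False)
        # the (along-curve, up, outward) frame handedness varies per span;
        # let the traversal fix the winding, then orient outward
        body.fix_normals()
        if body.volume < 0:
            body.invert()
        body.metadata["surface_index"] = sp["surface_index"]
        body.metadata["up"] = up
        body.metadata["outward"] = n3
        body.metadata["n_points"] = k
        bodies.append(body)
    if not bodies:
        raise ValueError("no non-bridge spans to attach a guiding feature to")
    return bodies


def contact_surface_widening(bone: trimesh.Trimesh, region_center: np.ndarray,
                             csw_thickness: float = 5.0,
                             csw_max_width: float = 30.0,
                             limit_surface=None,
                             patch_radius: float = 12.0,
                             tumor: trimesh.Trimesh | None = None,
                             margin: float = 10.0) -> trimesh.Trimesh:
    """Bone-conformal thickened patch (local contact-surface widening).

    Copies the bone triangles around ``region_center``, limited to within
    ``csw_max_width`` of the cut surface (the offset copy of the cutting
    surface acting as the width-limiting element), and thickens them
    ``csw_thickness`` outward along the vertex normals.
    """
    region_center = np.asarray(region_center, dtype=float)
    if tumor is not None:
        d = min_dist_to_triangles(
            region_center[None, :], np.ascontiguousarray(tumor.triangles))[0]
        if d < margin:
            raise ValueError(
                f"CSW region is {d:.1f} mm from the tumor, inside the "
                f"{margin:.0f} mm margin zone")
    centroids = bone.triangles_center
    sel = np.linalg.norm(centroids - region_center, axis=1) <= patch_radius
    if limit_surface is not None:
        g = (centroids - limit_surface.plane_point) @ limit_surface.plane_normal
        sel &= (g >= 0) & (g <= csw_max_width)
    if not sel.any():
        raise ValueError("empty CSW patch selection")
    face_idx = np.flatnonzero(sel)
    patch = bone.submesh([face_idx], append=True)
    # largest connected piece only
    parts = patch.split(only_watertight=False)
    if len(parts) > 1:
        patch = max(parts, key=lambda p: p.area)
    return _thicken_patch(patch, csw_thickness)


def _thicken_patch(patch: trimesh.Trimesh, thickness: float) -> trimesh.Trimesh:
    """Closed solid from an open surface patch: inner face (original),
    offset outer face, and side walls along every boundary loop."""
    vn = patch.vertex_normals
    inner = patch.vertices
    outer = inner + thickness * vn
    nv = len(inner)
    verts = np.vstack([inner, outer])
    faces = [patch.faces[:, ::-1], patch.faces + nv]  # inner flipped inward
    # boundary loops: edges referenced by exactly one face
    edges = patch.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = set(map(tuple, unique[counts == 1]))
    wall = []
    for e in patch.edges:
        if tuple(sorted(e)) in boundary:
            a, b = e  # oriented as in its face; the flipped bottom face
            # carries b->a, so the wall runs a->b to stay consistent
            wall += [[a, b, b + nv], [a, b + nv, a + nv]]
    if wall:
        faces.append(np.asarray(wall))
    solid = trimesh.Trimesh(vertices=verts, faces=np.vstack(faces), process=False)
    if solid.volume < 0:
        solid.invert()
    return solid


def deformable_clip(bone: trimesh.Trimesh, edge_point: np.ndarray,
                    edge_dir: np.ndarray,
                    clip_bridge_thickness: float = 5.0,
                    sphere_diameter: float = 10.0,
                    fit_clearance: float = 0.25,
                    max_edge_thickness: float = 12.0,
                    bridge_width: float = 8.0):
    """Deformable clip pinching a thin bone edge: two spheres straddling
    the edge linked by a thin bridge swept over the apex.

    ``edge_dir`` points from ``edge_point`` toward the free edge. Returns
    (solids, info) where info reports the measured edge thickness and the
    sphere gap (= thickness + 2 x fit clearance)."""
    edge_point = np.asarray(edge_point, dtype=float)
    edge_dir = np.asarray(edge_dir, dtype=float)
    edge_dir = edge_dir / np.linalg.norm(edge_dir)
    tris = np.ascontiguousarray(bone.triangles)
    # across-the-plate direction: dominant normal of the nearby side faces
    # (the nearest face alone can be the rounded crest, whose normal is
    # parallel to the edge direction and carries no sideways information)
    centroids = bone.triangles_center
    near = np.linalg.norm(centroids - edge_point, axis=1) < 10.0
    ns = bone.face_normals[near]
    ns = ns[np.abs(ns @ edge_dir) < 0.8]
    if len(ns) == 0:
        _, _, tid = closest_point_on_triangles(edge_point[None, :], tris)
        ns = bone.face_normals[tid]
    cov = ns.T @ ns
    w, v = np.linalg.eigh(cov)
    nh = v[:, -1]
    nh = nh - np.dot(nh, edge_dir) * edge_dir
    nh /= np.linalg.norm(nh)
    # local thickness: ray through the plate along the surface normal
    start = edge_point - 50.0 * nh
    ts = ray_mesh_hits(start, nh, tris)
    if len(ts) < 2:
        raise ValueError("cannot measure bone thickness at edge point")
    t_here = 50.0  # parameter of edge_point along the ray
    inside_pairs = [(ts[i], ts[i + 1]) for i in range(0, len(ts) - 1, 2)]
    pair = min(inside_pairs, key=lambda p: abs(0.5 * (p[0] + p[1]) - t_here))
    thickness = pair[1] - pair[0]
    if thickness > max_edge_thickness:
        raise ValueError(
            f"bone is {thickness:.1f} mm thick at the edge point; the clip "
            f"requires <= {max_edge_thickness:.0f} mm")
    # apex of the free edge along edge_dir
    ts_up = ray_mesh_hits(edge_point, edge_dir, tris)
    apex_h = float(ts_up[-1]) if len(ts_up) else 0.0
    mid = edge_point + 0.5 * (pair[0] + pair[1] - 2 * t_here) * nh
    R = sphere_diameter / 2.0
    d_c = thickness / 2.0 + fit_clearance + R
    half_b = clip_bridge_thickness / 2.0
    drop = max(d_c - half_b - 0.5, R * 0.5)
    center_h = apex_h - drop
    solids = []
    for sgn in (-1.0, 1.0):
        s = trimesh.creation.icosphere(subdivisions=3, radius=R)
        s.apply_translation(mid + sgn * d_c * nh + center_h * edge_dir)
        solids.append(s)
    # bridge: rectangle (thickness x width) swept along the arc over the apex
    along = np.cross(nh, edge_dir)
    along /= np.linalg.norm(along)
    arc_c = mid + center_h * edge_dir
    th = np.linspace(-np.pi / 2, np.pi / 2, 33)
    path = arc_c + d_c * (np.outer(np.sin(th), nh) + np.outer(np.cos(th), edge_dir))
    w = bridge_width / 2.0
    profile = np.array([[-half_b, -w], [half_b, -w], [half_b, w], [-half_b, w]])
    # densify profile edges for a better sweep
    prof = []
    for i in range(4):
        a, b = profile[i], profile[(i + 1) % 4]
        for t in np.linspace(0, 1, 4, endpoint=False):
            prof.append(a + t * (b - a))
    solids.append(_sweep(path, np.asarray(prof)))
    info = {
        "edge_thickness": float(thickness),
        "sphere_gap": float(2 * (d_c - R)),
        "bridge_thickness": float(clip_bridge_thickness),
    }
    return solids, info


def _annular_boss(base: np.ndarray, axis: np.ndarray, outer_r: float,
                  inner_r: float, length: float, n: int = 48) -> trimesh.Trimesh:
    """Drilled cylinder: watertight annular tube from base along axis."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(axis, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = np.outer(np.cos(th), u) + np.outer(np.sin(th), v)
    verts = np.vstack([
        base + outer_r * ring,
        base + outer_r * ring + length * axis,
        base + inner_r * ring,
        base + inner_r * ring + length * axis,
    ])
    O0, O1, I0, I1 = 0, n, 2 * n, 3 * n
    faces = []
    for j in range(n):
        jn = (j + 1) % n
        faces += [[O0 + j, O0 + jn, O1 + jn], [O0 + j, O1 + jn, O1 + j]]  # outer wall
        faces += [[I0 + j, I1 + jn, I0 + jn], [I0 + j, I1 + j, I1 + jn]]  # inner wall
        faces += [[O0 + j, I0 + jn, O0 + jn], [O0 + j, I0 + j, I0 + jn]]  # base cap
        faces += [[O1 + j, O1 + jn, I1 + jn], [O1 + j, I1 + jn, I1 + j]]  # top cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def fixation_features(surfaces: list, trajectory: GuideTrajectory,
                      approach: np.ndarray, params: GuideParams,
                      tumor: trimesh.Trimesh | None = None,
                      margin: float = 10.0, keep_out: list | None = None):
    """Drilled K-wire bosses with spherical anchors.

    Axes lie in the outer plane of the guiding feature of their span,
    tilted ``pin_tilt`` degrees from the approach at alternating azimuths
    so no two axes are parallel; axes must clear the tumor + margin zone
    and any keep-out boxes. Returns (solids, axes)."""
    approach = np.asarray(approach, dtype=float)
    approach /= np.linalg.norm(approach)
    solids = []
    axes = []
    tumor_tris = (np.ascontiguousarray(tumor.triangles)
                  if tumor is not None else None)
    n_placed = 0
    spans = [sp for sp in trajectory.spans if not sp["is_bridge"]]
    # longest spans first; very short fragments only get pins as a last resort
    spans.sort(key=lambda sp: -float(
        np.linalg.norm(np.diff(sp["points"], axis=0), axis=1).sum()))
    if params.pins_per_segment * len(spans) < 2 and len(spans) > 0:
        raise ValueError("need at least 2 fixation pins")
    for sp in spans:
        if (np.linalg.norm(np.diff(sp["points"], axis=0), axis=1).sum() < 12.0
                and n_placed >= 2):
            continue
        surf = surfaces[sp["surface_index"]]
        up = _surface_up(surf, approach)
        n3 = surf.plane_normal
        pts = sp["points"]
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        u = np.concatenate([[0.0], np.cumsum(d)])
        for pi in range(params.pins_per_segment):
            if n_placed >= params.max_pins:
                break
            frac = (pi + 1) / (params.pins_per_segment + 1)
            target = frac * u[-1]
            i = int(np.searchsorted(u, target))
            base_on_curve = pts[min(i, len(pts) - 1)]
            # base on the outer guiding plane, mid guiding height
            base = (base_on_curve + params.guiding_thickness * n3
                    + 0.5 * params.guiding_height * up)
            a_in_plane = approach - np.dot(approach, n3) * n3
            a_in_plane /= np.linalg.norm(a_in_plane)
            side = np.cross(n3, a_in_plane)
            placed = False
            # distinct in-plane azimuths: +-tilt, +-1.5 tilt, ... so that even
            # pins on coplanar guiding faces are never parallel
            k = n_placed // 2
            sgn0 = (-1.0) ** n_placed
            scale = 1.0 + 0.5 * k
            candidates = [sgn0 * scale, -sgn0 * scale,
                          sgn0 * (scale + 0.5), -sgn0 * (scale + 0.5)]
            for c in candidates:
                tilt = np.deg2rad(params.pin_tilt * c)
                axis = np.cos(tilt) * a_in_plane + np.sin(tilt) * side
                ok_sep = all(
                    np.degrees(np.arccos(np.clip(abs(np.dot(axis, ax[1])), -1, 1)))
                    >= params.min_pairwise_axis_angle for ax in axes)
                if ok_sep and _axis_clear(base, axis, tumor_tris, margin, keep_out):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "cannot place a fixation axis without violating the "
                    "tumor margin or a keep-out zone")
            boss = _annular_boss(
                base - 4.0 * axis, axis, params.fixation_outer / 2.0,
                params.fixation_inner / 2.0, params.fixation_length)
            anchor = trimesh.creation.icosphere(
                subdivisions=3, radius=params.fixation_anchor_diameter / 2.0)
            anchor.apply_translation(
                base + (params.fixation_length - 5.0) * axis)
            solids += [boss, anchor]
            axes.append((base, axis))
            n_placed += 1
    if len(axes) < 2:
        raise ValueError("need at least 2 fixation pins")
    return solids, axes


def _axis_clear(base, axis, tumor_tris, margin, keep_out) -> bool:
    samples = base[None, :] + np.linspace(-40.0, 30.0, 36)[:, None] * axis[None, :]
    if tumor_tris is not None:
        if min_dist_to_triangles(np.ascontiguousarray(samples), tumor_tris).min() < margin:
            return False
    for box in keep_out or []:
        lo = np.asarray(box[0], dtype=float)
        hi = np.asarray(box[1], dtype=float)
        inside = ((samples >= lo) & (samples <= hi)).all(axis=1)
        if inside.any():
            return False
    return True


def min_pairwise_angle(axes: list) -> float:
    """Smallest pairwise angle (degrees) between fixation axes."""
    worst = 180.0
    for i in range(len(axes)):
        for j in range(i + 1, len(axes)):
            c = abs(float(np.dot(axes[i][1], axes[j][1])))
            worst = min(worst, np.degrees(np.arccos(np.clip(c, -1, 1))))
    return worst


# ---------------------------------------------------------------------------
# finishing


def _voxelize_into(grid: VoxelGrid, mesh: trimesh.Trimesh):
    from ._voxel import voxelize

    return voxelize(mesh, grid.origin, grid.pitch, grid.shape)


def finish(bodies: dict, bone: trimesh.Trimesh, surfaces: list,
           trajectory: GuideTrajectory, approach: np.ndarray,
           params: GuideParams, pin_axes: list | None = None,
           csw_limits: list | None = None) -> SCGModel:
    """Unite all bodies, imprint the negative cortical bone shape, carve
    corner gaps at resection-plane junctions and the fixation bores, and
    emboss depth marks; returns a watertight printable model."""
    all_meshes = [m for v in bodies.values() for m in v]
    lo = np.min([m.bounds[0] for m in all_meshes], axis=0)
    hi = np.max([m.bounds[1] for m in all_meshes], axis=0)
    grid = VoxelGrid.empty(lo, hi, params.voxel_pitch, pad=3)
    for m in all_meshes:
        grid.add_mesh(m)
    # depth marks: embossed domes on the outer guiding face, every
    # depth_mark_spacing of blade travel along the span
    n_marks = 0
    for sp in trajectory.spans:
        if sp["is_bridge"]:
            continue
        surf = surfaces[sp["surface_index"]]
        up = _surface_up(surf, approach)
        n3 = surf.plane_normal
        pts = _resample_path(sp["points"], params.depth_mark_spacing)
        for p in pts[1:-1]:
            c = (p + 0.7 * params.guiding_height * up
                 + params.guiding_thickness * n3)
            grid.add_sphere(c, 1.2)
            n_marks += 1
    # CSW width limiting element: subtract beyond the offset cut surface
    for surf, width in csw_limits or []:
        grid.subtract_mask(grid.halfspace_mask(
            surf.plane_point + width * surf.plane_normal, surf.plane_normal))
    # negative cortical bone shape; one voxel of dilation gives the seating
    # clearance a printed guide needs (no penetration, sub-half-mm gap)
    from scipy import ndimage as _ndi

    bone_occ = _voxelize_into(grid, bone)
    bone_occ = _ndi.binary_dilation(bone_occ)
    grid.subtract_mask(bone_occ)
    # corner gaps: cylindrical clearance along every junction line
    n_gaps = 0
    for surf in surfaces:
        j = surf.junction_end
        if j is None:
            continue
        point, direction = j
        # center the clearance near the trajectory crossing
        node = trajectory.nodes[np.argmin(
            np.linalg.norm(trajectory.nodes - point
                           - np.outer((trajectory.nodes - point) @ direction,
                                      direction), axis=1))]
        t0 = np.dot(node - point, direction)
        center = point + t0 * direction
        grid.subtract_mask(grid.cylinder_mask(
            center, direction, params.corner_gap_radius,
            half_length=params.guiding_height + 12.0))
        n_gaps += 1
    # fixation bores survive the union
    for base, axis in pin_axes or []:
        grid.subtract_mask(grid.cylinder_mask(
            base, axis, params.fixation_inner / 2.0,
            half_length=params.fixation_length + 10.0))
    solid = grid.to_mesh()
    parts = solid.split(only_watertight=False)
    if len(parts) > 1:
        solid = max(parts, key=lambda p: p.volume)
    contact = _contact_region(solid, bone, tol=2.0 * params.voxel_pitch)
    qc = qc_mesh(solid, check_self_intersections=False)
    meta = {
        "n_corner_gaps": n_gaps,
        "n_depth_marks": n_marks,
        "n_nodes": len(trajectory.nodes),
        "voxel_pitch": params.voxel_pitch,
        "qc": qc.to_dict(),
    }
    return SCGModel(solid=solid, bodies=bodies, pin_axes=list(pin_axes or []),
                    contact_region=contact, params=params, metadata=meta)


def _contact_region(solid: trimesh.Trimesh, bone: trimesh.Trimesh,
                    tol: float) -> trimesh.Trimesh:
    """Subset of guide faces lying on the bone surface (the negative-shape
    seat)."""
    from scipy.spatial import cKDTree

    from .meshproc import surface_distance

    centroids = solid.triangles_center
    upper = cKDTree(bone.vertices).query(centroids, workers=-1)[0]
    cand = np.flatnonzero(upper <= tol + 2.0)
    if len(cand) == 0:
        raise ValueError("empty contact region")
    d = surface_distance(centroids[cand], bone)
    sel = cand[np.flatnonzero(d <= tol)]
    if len(sel) == 0:
        raise ValueError("empty contact region")
    return solid.submesh([sel], append=True)


def export_guide(scg: SCGModel, path) -> None:
    """Binary STL export (mm); refuses non-watertight solids."""
    if not scg.solid.is_watertight:
        raise ValueError("refusing to export a non-watertight guide")
    scg.solid.export(str(path))
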