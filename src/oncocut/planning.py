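"""Geometrical definition of the resection: approach plane, tumor
silhouette, oncologic margin offset, polyline trajectory and extruded cut
surfaces.

The surgical intent enters as a 3-point approach plane and a margin budget
(oncologic margin + blade kerf). The tumor is projected orthographically
onto the plane; the outer silhouette is expanded by the total offset; the
resection polyline is fitted outside that expanded region (or supplied by
the user) and extruded along the approach direction with a draft angle so
the resected piece tapers like a cork and extracts freely. A final 3D
validation pushes segments outward until the true tumor-to-surface
distance honors the margin on every cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon, LineString, Point

from ._dist import min_dist_to_triangles
from .meshproc import surface_distance

__all__ = [
    "ApproachPlane",
    "ResectionPlan",
    "ResectionSurface",
    "plane_from_points",
    "silhouette",
    "offset_margin",
    "fit_polyline",
    "extrude_resection_surfaces",
    "validate_plan",
]

DEFAULT_MARGIN = 10.0  # mm, oncologic baseline
DEFAULT_BLADE = 2.0  # mm, saw kerf folded into the planning offset
DEFAULT_DRAFT = 5.0  # degrees


@dataclass
class ApproachPlane:
    """Plane of the main surgical direction with an in-plane 2D basis."""

    origin: np.ndarray
    normal: np.ndarray  # unit, the approach direction
    basis_u: np.ndarray
    basis_v: np.ndarray

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.origin
        return np.column_stack([d @ self.basis_u, d @ self.basis_v])

    def to_3d(self, uv: np.ndarray, height: float = 0.0) -> np.ndarray:
        uv = np.atleast_2d(uv)
        return (self.origin + np.outer(uv[:, 0], self.basis_u)
                + np.outer(uv[:, 1], self.basis_v) + height * self.normal)

    def height(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.normal


def plane_from_points(p1, p2, p3) -> ApproachPlane:
    """Approach plane through three points; normal by the right-hand rule on
    (p2-p1, p3-p1)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * max(np.linalg.norm(p2 - p1), 1.0):
        raise ValueError("points are collinear")
    n = n / norm
    u = (p2 - p1) / np.linalg.norm(p2 - p1)
    v = np.cross(n, u)
    return ApproachPlane(origin=p1, normal=n, basis_u=u, basis_v=v)


@dataclass
class ResectionSurface:
    """One planar ruled cut surface per polyline segment."""

    mesh: trimesh.Trimesh
    plane_point: np.ndarray  # a point on the (infinite) cut plane
    plane_normal: np.ndarray  # unit, pointing away from the resected piece
    segment_index: int
    seg_a2d: np.ndarray  # base segment endpoints in approach-plane coords
    seg_b2d: np.ndarray
    junction_start: np.ndarray | None = None  # (point, direction) with neighbor
    junction_end: np.ndarray | None = None

    @property
    def inward_normal(self) -> np.ndarray:
        """Unit normal toward the resected piece."""
        return -self.plane_normal

    def sample(self, n: int = 10_000, rng=None) -> np.ndarray:
        """Uniform surface samples (vertices of a dense parametric grid)."""
        v = self.mesh.vertices
        f = self.mesh.faces
        rng = rng or np.random.default_rng(0)
        tri = v[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        idx = rng.choice(len(f), size=n, p=areas / areas.sum())
        r1 = np.sqrt(rng.random(n))
        r2 = rng.random(n)
        a, b, c = tri[idx, 0], tri[idx, 1], tri[idx, 2]
        return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


@dataclass
class ResectionPlan:
    plane: ApproachPlane
    oncologic_margin: float = DEFAULT_MARGIN
    blade_thickness: float = DEFAULT_BLADE
    draft_angle: float = DEFAULT_DRAFT
    polyline: np.ndarray = None  # (n+1, 2) vertices in plane coordinates
    extrusion_depth: float | None = None
    start_height: float | None = None  # along -normal from the plane
    segment_margins: dict = dc_field(default_factory=dict)  # per-segment override
    surfaces: list = dc_field(default_factory=list)

    def __post_init__(self):
        if self.draft_angle < 0:
            raise ValueError("draft_angle must be >= 0")
        if self.polyline is not None:
            self.polyline = np.asarray(self.polyline, dtype=float)
            nseg = len(self.polyline) - 1
            if not (1 <= nseg <= 4):
                raise ValueError("polyline must have 1 to 4 segments")

    @property
    def total_offset(self) -> float:
        return self.oncologic_margin + self.blade_thickness

    @property
    def n_segments(self) -> int:
        return 0 if self.polyline is None else len(self.polyline) - 1

    def margin_for(self, segment_index: int) -> float:
        return float(self.segment_margins.get(segment_index, self.oncologic_margin))


def silhouette(tumor: trimesh.Trimesh, plane: ApproachPlane) -> Polygon:
    """Outer boundary of the orthographic projection of the tumor onto the
    approach plane (union of projected triangles; interior holes dropped)."""
    if len(tumor.faces) == 0:
        raise ValueError("empty tumor mesh")
    uv = plane.to_2d(tumor.vertices)
    tris = uv[tumor.faces]
    # drop degenerate (edge-on) projections
    areas = 0.5 * np.abs(
        (tris[:, 1, 0] - tris[:, 0, 0]) * (tris[:, 2, 1] - tris[:, 0, 1])
        - (tris[:, 2, 0] - tris[:, 0, 0]) * (tris[:, 1, 1] - tris[:, 0, 1]))
    polys = shapely.polygons(tris[areas > 1e-12])
    union = shapely.union_all(shapely.make_valid(polys))
    if union.geom_type == "MultiPolygon":
        union = max(union.geoms, key=lambda g: g.area)
    return Polygon(union.exterior)


def offset_margin(polygon: Polygon, total_offset: float,
                  quad_segs: int = 64) -> Polygon:
    """Outward Minkowski offset of the silhouette by the margin budget."""
    if total_offset < 0:
        raise ValueError("total_offset must be >= 0")
    if not polygon.is_valid:
        raise ValueError("input polygon is self-intersecting")
    if total_offset == 0:
        return polygon
    return polygon.buffer(total_offset, quad_segs=quad_segs,
                          join_style="round")


def _support_line(poly_pts: np.ndarray, direction: np.ndarray):
    """Outer tangent line of a point cloud with outward normal ``direction``:
    returns (point_on_line, line_direction)."""
    h = poly_pts @ direction
    i = int(np.argmax(h))
    tangent = np.array([-direction[1], direction[0]])
    return poly_pts[i], tangent


def fit_polyline(offset_polygon: Polygon, n_segments: int,
                 resect_dir: np.ndarray, bone_uv: np.ndarray,
                 span_per_joint: float = 35.0) -> np.ndarray:
    """Fit an open polyline of ``n_segments`` chords tangent to the expanded
    silhouette, facing the side of the bone being resected.

    Each segment lies on a support line of the convex hull of the offset
    polygon, so every polyline point keeps at least the planned offset from
    the tumor silhouette. ``resect_dir`` is the in-plane unit direction from
    the bone toward the tumor (the side of the piece); endpoints are
    extended beyond the projected bone extent for through-cuts.
    """
    if not (1 <= n_segments <= 4):
        raise ValueError("n_segments must be between 1 and 4")
    pts = np.asarray(offset_polygon.exterior.coords)
    d = np.asarray(resect_dir, dtype=float)
    d = d / np.linalg.norm(d)
    theta0 = np.arctan2(d[1], d[0])
    if n_segments == 1:
        angles = np.array([theta0])
    else:
        span = np.deg2rad(span_per_joint) * (n_segments - 1)
        angles = theta0 + np.linspace(-span / 2, span / 2, n_segments)
    lines = []
    for th in angles:
        m = np.array([np.cos(th), np.sin(th)])
        p, t = _support_line(pts, m)
        lines.append((p, t, m))
    # interior vertices: intersections of consecutive support lines
    verts = []
    for (p1, t1, _), (p2, t2, _) in zip(lines[:-1], lines[1:]):
        A = np.column_stack([t1, -t2])
        try:
            s = np.linalg.solve(A, p2 - p1)
        except np.linalg.LinAlgError:
            raise ValueError("adjacent support lines are parallel") from None
        verts.append(p1 + s[0] * t1)
    # endpoints: extend the first/last line beyond the bone's projected extent
    center = bone_uv.mean(axis=0)
    reach = float(np.linalg.norm(bone_uv - center, axis=1).max()) + 10.0
    p_first, t_first, m_first = lines[0]
    p_last, t_last, m_last = lines[-1]
    anchor_first = verts[0] if verts else p_first
    anchor_last = verts[-1] if verts else p_last
    # chain runs counter-clockwise in support angle; extend outward both ways
    start = anchor_first - t_first * (reach + np.linalg.norm(anchor_first - center))
    end = anchor_last + t_last * (reach + np.linalg.norm(anchor_last - center))
    poly = np.array([start] + verts + [end])
    if _self_intersects(poly):
        raise ValueError("fitted polyline self-intersects; reduce span or segments")
    hull_r = np.linalg.norm(pts - center, axis=1).max()
    if np.linalg.norm(poly - center, axis=1).max() > 20 * (hull_r + reach):
        raise ValueError("offset polygon exceeds the bone extent")
    return poly


def _self_intersects(polyline: np.ndarray) -> bool:
    return not LineString(polyline).is_simple


def extrude_resection_surfaces(plan: ResectionPlan, bone: trimesh.Trimesh | None = None,
                               tumor_uv_centroid: np.ndarray | None = None,
                               n_subdiv: int = 32) -> list:
    """Extrude every polyline segment along the negative approach normal to
    the extrusion depth, tilted by the draft angle so the piece tapers with
    depth (the taper eases extraction of the resected cork).

    Each surface is planar; adjacent surfaces share their junction line
    exactly. ``bone`` (or preset start/depth in the plan) fixes the
    extrusion window so cuts are through-cuts.
    """
    if plan.polyline is None:
        raise ValueError("plan has no polyline")
    plane = plan.plane
    if plan.start_height is None or plan.extrusion_depth is None:
        if bone is None:
            raise ValueError("need bone mesh (or explicit start/depth) to size the extrusion")
        h = plane.height(bone.vertices)
        if plan.start_height is None:
            plan.start_height = float(h.max()) + 5.0
        if plan.extrusion_depth is None:
            plan.extrusion_depth = float(h.max() - h.min()) + 20.0
    if plan.extrusion_depth <= 0:
        raise ValueError("extrusion depth must be positive")

    if tumor_uv_centroid is None:
        tumor_uv_centroid = np.zeros(2)
    tan_a = np.tan(np.deg2rad(plan.draft_angle))
    surfaces = []
    poly = plan.polyline
    for i in range(plan.n_segments):
        a2, b2 = poly[i], poly[i + 1]
        t2 = b2 - a2
        t2 = t2 / np.linalg.norm(t2)
        m2 = np.array([t2[1], -t2[0]])  # in-plane normal; orient away from piece
        if np.dot(tumor_uv_centroid - a2, m2) > 0:
            m2 = -m2
        s_grid = np.linspace(0.0, plan.extrusion_depth, n_subdiv + 1)
        rows = []
        for s in s_grid:
            shift = -tan_a * s * m2  # plane creeps toward the piece with depth
            h = plan.start_height - s
            rows.append(plane.to_3d(np.array([a2 + shift, b2 + shift]), height=h))
        rows = np.asarray(rows)  # (n+1, 2, 3)
        verts = rows.reshape(-1, 3)
        faces = []
        for r in range(n_subdiv):
            i0, i1, i2, i3 = 2 * r, 2 * r + 1, 2 * r + 2, 2 * r + 3
            faces += [[i0, i1, i3], [i0, i3, i2]]
        mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
        # plane normal away from the piece: in-plane part m2 plus draft tilt
        e1 = rows[0, 1] - rows[0, 0]
        e2 = rows[-1, 0] - rows[0, 0]
        n3 = np.cross(e1, e2)
        n3 /= np.linalg.norm(n3)
        m3 = plane.to_3d(np.array([m2]))[0] - plane.origin
        if np.dot(n3, m3) < 0:
            n3 = -n3
        surfaces.append(ResectionSurface(
            mesh=mesh, plane_point=rows[0, 0], plane_normal=n3,
            segment_index=i, seg_a2d=a2.copy(), seg_b2d=b2.copy()))
    _attach_junctions(surfaces)
    return surfaces


def _attach_junctions(surfaces: list) -> None:
    """Junction line between adjacent planar surfaces (plane-plane
    intersection through the shared polyline vertex)."""
    for s0, s1 in zip(surfaces[:-1], surfaces[1:]):
        direction = np.cross(s0.plane_normal, s1.plane_normal)
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            continue
        direction /= nrm
        # a point on both planes: solve the 2x3 underdetermined system near
        # the shared top vertex of the two surface meshes
        p0 = s0.mesh.vertices[2]  # top row, shared vertex (b of s0 = a of s1)
        A = np.vstack([s0.plane_normal, s1.plane_normal])
        b = np.array([np.dot(s0.plane_normal, s0.plane_point),
                      np.dot(s1.plane_normal, s1.plane_point)])
        point = np.linalg.lstsq(
            np.vstack([A, direction]), np.append(b, np.dot(direction, p0)),
            rcond=None)[0]
        s0.junction_end = (point, direction)
        s1.junction_start = (point, direction)


def validate_plan(plan: ResectionPlan, tumor: trimesh.Trimesh,
                  bone: trimesh.Trimesh | None = None,
                  tumor_uv_centroid: np.ndarray | None = None,
                  step: float = 0.5, max_iters: int = 20,
                  n_samples: int = 10_000) -> dict:
    """Verify (and enforce) the true 3D margin on every cut surface.

    The minimum distance between the tumor surface and each cut surface is
    measured by dense sampling plus the exact tumor-vertex minimum; any
    segment violating its margin (global baseline or per-segment override)
    is pushed outward in 0.5 mm steps, compensating the margin the draft
    tilt consumes with depth. Returns a report with achieved minima.
    """
    if not plan.surfaces:
        plan.surfaces = extrude_resection_surfaces(
            plan, bone=bone, tumor_uv_centroid=tumor_uv_centroid)
    tumor_pts = np.asarray(tumor.vertices, dtype=np.float64)
    expanded = np.zeros(plan.n_segments)
    for it in range(max_iters + 1):
        mins = _surface_margins(plan.surfaces, tumor, tumor_pts, n_samples)
        bad = [i for i in range(plan.n_segments)
               if mins[i] < plan.margin_for(i) - 1e-9]
        if not bad or it == max_iters:
            break
        poly = plan.polyline.copy()
        for i in bad:
            a2, b2 = poly[i], poly[i + 1]
            t2 = b2 - a2
            t2 /= np.linalg.norm(t2)
            m2 = np.array([t2[1], -t2[0]])
            if tumor_uv_centroid is not None and np.dot(tumor_uv_centroid - a2, m2) > 0:
                m2 = -m2
            poly[i] = poly[i] + step * m2
            poly[i + 1] = poly[i + 1] + step * m2
            expanded[i] += step
        plan.polyline = poly
        plan.surfaces = extrude_resection_surfaces(
            plan, bone=bone, tumor_uv_centroid=tumor_uv_centroid)
    satisfied = all(mins[i] >= plan.margin_for(i) - 1e-9
                    for i in range(plan.n_segments))
    return {
        "achieved_margin": {i: float(mins[i]) for i in range(plan.n_segments)},
        "required_margin": {i: plan.margin_for(i) for i in range(plan.n_segments)},
        "expanded_by": {i: float(expanded[i]) for i in range(plan.n_segments)},
        "satisfied": bool(satisfied),
    }


def _surface_margins(surfaces, tumor, tumor_pts, n_samples) -> np.ndarray:
    mins = np.empty(len(surfaces))
    for i, surf in enumerate(surfaces):
        tris = np.ascontiguousarray(surf.mesh.triangles, dtype=np.float64)
        d_vert = min_dist_to_triangles(tumor_pts, tris).min()
        samples = surf.sample(n=n_samples, rng=np.random.default_rng(7 + i))
        d_samp = surface_distance(samples, tumor).min()
        mins[i] = min(d_vert, d_samp)
    return mins
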