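"""Dimension measurements on generated guide geometry.

Every printed design dimension (sweep diameter, anchor diameter, guiding
height and thickness, CSW thickness, fixation bore, draft angle, silhouette
offset) is measured back from the built bodies rather than read from the
parameters, so conformance checks exercise the construction itself.
"""

from __future__ import annotations

import numpy as np
import trimesh
from shapely.geometry import LineString

__all__ = [
    "sweep_diameter",
    "anchor_diameter",
    "guiding_height",
    "guiding_thickness",
    "patch_thickness",
    "bore_diameter",
    "draft_angle",
    "silhouette_offset",
]


def sweep_diameter(main_body: trimesh.Trimesh, trajectory) -> float:
    """Cross-section diameter of the swept tube, measured perpendicular to
    the trajectory at the midpoint of the longest span."""
    span = max((s for s in trajectory.spans if not s["is_bridge"]),
               key=lambda s: float(np.linalg.norm(
                   np.diff(s["points"], axis=0), axis=1).sum()))
    pts = span["points"]
    i = len(pts) // 2
    p = pts[i]
    tangent = pts[min(i + 1, len(pts) - 1)] - pts[max(i - 1, 0)]
    tangent = tangent / np.linalg.norm(tangent)
    segs = trimesh.intersections.mesh_plane(main_body, tangent, p)
    if len(segs) == 0:
        raise ValueError("section plane misses the main body")
    sect = segs.reshape(-1, 3)
    # keep the ring around p (exclude other parts of the sweep the plane hits)
    r = np.linalg.norm(sect - p, axis=1)
    ring = sect[r < 1.5 * r.min() + 10.0]
    return 2.0 * float(np.linalg.norm(ring - p, axis=1).max())


def anchor_diameter(anchor: trimesh.Trimesh) -> float:
    """Maximum chord of a node anchor sphere."""
    v = np.asarray(anchor.vertices)
    c = v.mean(axis=0)
    return 2.0 * float(np.linalg.norm(v - c, axis=1).max())


def guiding_height(guiding_body: trimesh.Trimesh) -> float:
    """Height of the guiding flange measured along the cut surface."""
    k = guiding_body.metadata["n_points"]
    v = np.asarray(guiding_body.vertices)
    return float(np.linalg.norm(v[k:2 * k] - v[:k], axis=1).mean())


def guiding_thickness(guiding_body: trimesh.Trimesh) -> float:
    """Thickness of the guiding flange normal to the cut surface."""
    k = guiding_body.metadata["n_points"]
    v = np.asarray(guiding_body.vertices)
    return float(np.linalg.norm(v[2 * k:3 * k] - v[:k], axis=1).mean())


def patch_thickness(csw_body: trimesh.Trimesh) -> float:
    """Thickness of a bone-conformal thickened patch (inner face to outer
    face along the vertex normals)."""
    v = np.asarray(csw_body.vertices)
    nv = len(v) // 2
    return float(np.linalg.norm(v[nv:] - v[:nv], axis=1).mean())


def bore_diameter(boss: trimesh.Trimesh, axis_point: np.ndarray,
                  axis_dir: np.ndarray) -> float:
    """Diameter of the through-hole of a drilled fixation cylinder: twice
    the closest vertex distance from the axis."""
    v = np.asarray(boss.vertices) - np.asarray(axis_point)
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    radial = v - np.outer(v @ d, d)
    return 2.0 * float(np.linalg.norm(radial, axis=1).min())


def draft_angle(surface, approach: np.ndarray) -> float:
    """Angle (degrees) between a cut surface and the approach direction,
    recomputed from the surface mesh geometry."""
    mesh = surface.mesh
    a = np.asarray(approach, dtype=float)
    a = a / np.linalg.norm(a)
    e1 = mesh.vertices[1] - mesh.vertices[0]
    e2 = mesh.vertices[-2] - mesh.vertices[0]
    n = np.cross(e1, e2)
    n = n / np.linalg.norm(n)
    return float(np.degrees(np.arcsin(abs(np.dot(n, a)))))


def silhouette_offset(silhouette_poly, offset_poly, n_samples: int = 2000) -> float:
    """Minimum distance between the expanded polygon boundary and the tumor
    silhouette, by dense boundary sampling."""
    ring = LineString(silhouette_poly.exterior.coords)
    out = LineString(offset_poly.exterior.coords)
    ts = np.linspace(0.0, out.length, n_samples, endpoint=False)
    d = [out.interpolate(t).distance(ring) for t in ts]
    return float(min(d))
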