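"""Low-level exact distance and containment kernels.

Numba-compiled point/triangle and ray/mesh primitives shared by the QC,
planning and validation layers. All inputs are float64 arrays in mm;
triangles are given as an (F, 3, 3) array of corner coordinates.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = [
    "closest_point_on_triangles",
    "min_dist_to_triangles",
    "points_in_mesh",
    "signed_dist_to_mesh",
    "ray_mesh_hits",
]


@njit(cache=True, fastmath=False)
def _pt_tri_sq(p, a, b, c):
    """Squared distance from point p to triangle (a, b, c) (Eberly's region test)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab[0] * ap[0] + ab[1] * ap[1] + ab[2] * ap[2]
    d2 = ac[0] * ap[0] + ac[1] * ap[1] + ac[2] * ap[2]
    if d1 <= 0.0 and d2 <= 0.0:
        q = a
        return (
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2,
            q[0], q[1], q[2],
        )
    bp = p - b
    d3 = ab[0] * bp[0] + ab[1] * bp[1] + ab[2] * bp[2]
    d4 = ac[0] * bp[0] + ac[1] * bp[1] + ac[2] * bp[2]
    if d3 >= 0.0 and d4 <= d3:
        q = b
        return (
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2,
            q[0], q[1], q[2],
        )
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        qx = a[0] + v * ab[0]
        qy = a[1] + v * ab[1]
        qz = a[2] + v * ab[2]
        return ((p[0] - qx) ** 2 + (p[1] - qy) ** 2 + (p[2] - qz) ** 2, qx, qy, qz)
    cp = p - c
    d5 = ab[0] * cp[0] + ab[1] * cp[1] + ab[2] * cp[2]
    d6 = ac[0] * cp[0] + ac[1] * cp[1] + ac[2] * cp[2]
    if d6 >= 0.0 and d5 <= d6:
        q = c
        return (
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2,
            q[0], q[1], q[2],
        )
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        qx = a[0] + w * ac[0]
        qy = a[1] + w * ac[1]
        qz = a[2] + w * ac[2]
        return ((p[0] - qx) ** 2 + (p[1] - qy) ** 2 + (p[2] - qz) ** 2, qx, qy, qz)
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        qx = b[0] + w * (c[0] - b[0])
        qy = b[1] + w * (c[1] - b[1])
        qz = b[2] + w * (c[2] - b[2])
        return ((p[0] - qx) ** 2 + (p[1] - qy) ** 2 + (p[2] - qz) ** 2, qx, qy, qz)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    qx = a[0] + v * ab[0] + w * ac[0]
    qy = a[1] + v * ab[1] + w * ac[1]
    qz = a[2] + v * ab[2] + w * ac[2]
    return ((p[0] - qx) ** 2 + (p[1] - qy) ** 2 + (p[2] - qz) ** 2, qx, qy, qz)


@njit(cache=True, parallel=True)
def closest_point_on_triangles(points, tris):
    """For every query point return (distance, closest point, triangle index)."""
    n = points.shape[0]
    dist = np.empty(n)
    closest = np.empty((n, 3))
    tri_id = np.empty(n, dtype=np.int64)
    for i in prange(n):
        best = np.inf
        bx = by = bz = 0.0
        bt = -1
        p = points[i]
        for f in range(tris.shape[0]):
            d2, qx, qy, qz = _pt_tri_sq(p, tris[f, 0], tris[f, 1], tris[f, 2])
            if d2 < best:
                best = d2
                bx, by, bz = qx, qy, qz
                bt = f
        dist[i] = np.sqrt(best)
        closest[i, 0] = bx
        closest[i, 1] = by
        closest[i, 2] = bz
        tri_id[i] = bt
    return dist, closest, tri_id


@njit(cache=True, parallel=True)
def min_dist_to_triangles(points, tris):
    """Unsigned distance from each point to the triangle soup."""
    n = points.shape[0]
    dist = np.empty(n)
    for i in prange(n):
        best = np.inf
        p = points[i]
        for f in range(tris.shape[0]):
            d2, _, _, _ = _pt_tri_sq(p, tris[f, 0], tris[f, 1], tris[f, 2])
            if d2 < best:
                best = d2
        dist[i] = np.sqrt(best)
    return dist


@njit(cache=True)
def _ray_crossings(ox, oy, oz, tris):
    """Count crossings of the +z ray from (ox, oy, oz) with the triangle soup.

    Uses 2D barycentric tests in the xy-plane with a half-open rule; callers
    jitter the origin off lattice alignments for robustness.
    """
    count = 0
    for f in range(tris.shape[0]):
        ax, ay, az = tris[f, 0, 0], tris[f, 0, 1], tris[f, 0, 2]
        bx, by, bz = tris[f, 1, 0], tris[f, 1, 1], tris[f, 1, 2]
        cx, cy, cz = tris[f, 2, 0], tris[f, 2, 1], tris[f, 2, 2]
        d = (by - ay) * (cx - ax) - (bx - ax) * (cy - ay)
        if d == 0.0:
            continue
        u = ((oy - ay) * (cx - ax) - (ox - ax) * (cy - ay)) / d
        v = ((bx - ax) * (oy - ay) - (by - ay) * (ox - ax)) / -d
        if u < 0.0 or v < 0.0 or u + v > 1.0:
            continue
        z = az + u * (bz - az) + v * (cz - az)
        if z > oz:
            count += 1
    return count


@njit(cache=True, parallel=True)
def points_in_mesh(points, tris):
    """Ray-parity containment test (watertight solids)."""
    n = points.shape[0]
    inside = np.empty(n, dtype=np.bool_)
    for i in prange(n):
        # tiny irrational jitter avoids rays exactly through edges/vertices
        c = _ray_crossings(
            points[i, 0] + 1.13e-5, points[i, 1] + 2.71e-5, points[i, 2], tris
        )
        inside[i] = (c % 2) == 1
    return inside


def signed_dist_to_mesh(points, tris):
    """Signed distance to a watertight mesh: negative inside the solid."""
    d = min_dist_to_triangles(points, tris)
    sign = np.where(points_in_mesh(points, tris), -1.0, 1.0)
    return sign * d


@njit(cache=True)
def ray_mesh_hits(origin, direction, tris):
    """Sorted parametric hits t >= 0 of origin + t * direction with the soup
    (Moller-Trumbore)."""
    hits = []
    ox, oy, oz = origin[0], origin[1], origin[2]
    dx, dy, dz = direction[0], direction[1], direction[2]
    for f in range(tris.shape[0]):
        a = tris[f, 0]
        e1 = tris[f, 1] - a
        e2 = tris[f, 2] - a
        px = dy * e2[2] - dz * e2[1]
        py = dz * e2[0] - dx * e2[2]
        pz = dx * e2[1] - dy * e2[0]
        det = e1[0] * px + e1[1] * py + e1[2] * pz
        if abs(det) < 1e-12:
            continue
        inv = 1.0 / det
        tx, ty, tz = ox - a[0], oy - a[1], oz - a[2]
        u = (tx * px + ty * py + tz * pz) * inv
        if u < 0.0 or u > 1.0:
            continue
        qx = ty * e1[2] - tz * e1[1]
        qy = tz * e1[0] - tx * e1[2]
        qz = tx * e1[1] - ty * e1[0]
        v = (dx * qx + dy * qy + dz * qz) * inv
        if v < 0.0 or u + v > 1.0:
            continue
        t = (e2[0] * qx + e2[1] * qy + e2[2] * qz) * inv
        if t >= 0.0:
            hits.append(t)
    out = np.array(hits)
    return np.sort(out)
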