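"""Independent brute-force oracles used to cross-check the package's
accelerated geometry kernels. Pure numpy, O(V*F), written against the
textbook definitions rather than the implementation's code paths."""

import struct

import numpy as np


def point_triangle_distance(p, a, b, c):
    """Exact distance from a point to one triangle: the closest point is the
    in-plane projection when its barycentric coordinates are nonnegative,
    otherwise the closest point on one of the three edges."""
    candidates = []
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn > 0:
        n = n / nn
        proj = p - np.dot(p - a, n) * n
        # barycentric test
        v0, v1, v2 = b - a, c - a, proj - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        if den != 0:
            u = (d11 * d20 - d01 * d21) / den
            w = (d00 * d21 - d01 * d20) / den
            if u >= 0 and w >= 0 and u + w <= 1:
                candidates.append(np.linalg.norm(p - proj))
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d = e1 - e0
        t = np.clip(np.dot(p - e0, d) / np.dot(d, d), 0.0, 1.0)
        candidates.append(np.linalg.norm(p - (e0 + t * d)))
    return min(candidates)


def min_dist_brute(points, tris):
    """O(V*F) minimum distance from each point to a triangle soup."""
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = min(point_triangle_distance(p, t[0], t[1], t[2]) for t in tris)
    return out


def hausdorff_brute(mesh_a, mesh_b):
    """One-sided vertex-to-surface Hausdorff by brute force."""
    d = min_dist_brute(np.asarray(mesh_a.vertices),
                       np.asarray(mesh_b.triangles))
    return {"max": float(d.max()), "mean": float(np.abs(d).mean())}


def rasterize_polygon_area(tris_2d, pixel=0.1):
    """Area of the union of 2D triangles by pixel counting."""
    tris_2d = np.asarray(tris_2d)
    lo = tris_2d.reshape(-1, 2).min(axis=0) - pixel
    hi = tris_2d.reshape(-1, 2).max(axis=0) + pixel
    nx = int(np.ceil((hi[0] - lo[0]) / pixel))
    ny = int(np.ceil((hi[1] - lo[1]) / pixel))
    grid = np.zeros((nx, ny), dtype=bool)
    xs = lo[0] + pixel * (np.arange(nx) + 0.5)
    ys = lo[1] + pixel * (np.arange(ny) + 0.5)
    for a, b, c in tris_2d:
        d = (b[1] - a[1]) * (c[0] - a[0]) - (b[0] - a[0]) * (c[1] - a[1])
        if d == 0:
            continue
        i0 = max(0, int((min(a[0], b[0], c[0]) - lo[0]) / pixel) - 1)
        i1 = min(nx, int((max(a[0], b[0], c[0]) - lo[0]) / pixel) + 2)
        j0 = max(0, int((min(a[1], b[1], c[1]) - lo[1]) / pixel) - 1)
        j1 = min(ny, int((max(a[1], b[1], c[1]) - lo[1]) / pixel) + 2)
        px, py = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        u = ((py - a[1]) * (c[0] - a[0]) - (px - a[0]) * (c[1] - a[1])) / d
        v = ((b[0] - a[0]) * (py - a[1]) - (b[1] - a[1]) * (px - a[0])) / -d
        grid[i0:i1, j0:j1] |= (u >= 0) & (v >= 0) & (u + v <= 1)
    return grid.sum() * pixel * pixel


def read_binary_stl(path):
    """Minimal independent binary-STL reader (header + triangle records)."""
    with open(path, "rb") as fh:
        fh.read(80)
        (n,) = struct.unpack("<I", fh.read(4))
        tris = np.empty((n, 3, 3), dtype=np.float64)
        for i in range(n):
            rec = struct.unpack("<12fH", fh.read(50))
            tris[i] = np.asarray(rec[3:12]).reshape(3, 3)
    return tris


def point_in_mesh_ray(points, mesh, direction=(0.17, 0.39, 0.91)):
    """Ray-parity containment oracle using an oblique ray direction and
    Moller-Trumbore intersection, independent of the package kernels."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    tris = np.asarray(mesh.triangles)
    out = np.zeros(len(points), dtype=bool)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    good = np.abs(det) > 1e-12
    for k, p in enumerate(np.asarray(points, dtype=float)):
        tvec = p - tris[:, 0]
        u = np.einsum("ij,ij->i", tvec, pvec) / np.where(good, det, 1.0)
        qvec = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", d, qvec) / np.where(good, det, 1.0)
        t = np.einsum("ij,ij->i", e2, qvec) / np.where(good, det, 1.0)
        hits = good & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
        out[k] = hits.sum() % 2 == 1
    return out
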