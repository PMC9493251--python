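"""Mesh QC and simplification (the STL processing stage).

Surface meshes are carried as :class:`trimesh.Trimesh` objects with vertices
in mm. Decimation is quadric edge collapse (exact face-count targets on
closed manifolds); Hausdorff distances are exact point-to-surface distances
sampled on all vertices, accelerated with KD-tree candidate pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import trimesh
from numba import njit, prange
from scipy.spatial import cKDTree

from ._dist import _pt_tri_sq, min_dist_to_triangles
from ._qem import simplify_mesh_arrays

__all__ = [
    "MeshQCReport",
    "qc_mesh",
    "decimate",
    "hausdorff",
    "surface_distance",
    "load_mesh",
    "save_mesh",
]


@dataclass
class MeshQCReport:
    watertight: bool
    manifold: bool
    n_components: int
    n_faces: int
    self_intersections: int
    min_edge: float

    def to_dict(self):
        return asdict(self)


def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load_mesh(str(path))
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"not a triangle mesh: {path}")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))


def qc_mesh(mesh: trimesh.Trimesh, check_self_intersections: bool = True,
            max_faces_for_intersection: int = 300_000) -> MeshQCReport:
    """Compute the QC report: watertightness (every edge in exactly two faces
    with consistent winding), edge-manifoldness, component and face counts,
    self-intersection count and minimum edge length."""
    edges = mesh.edges_sorted
    if len(edges):
        _, counts = np.unique(edges, axis=0, return_counts=True)
        manifold = bool(counts.max(initial=0) <= 2)
        closed = bool((counts == 2).all())
    else:
        manifold = True
        closed = False
    watertight = closed and bool(mesh.is_winding_consistent)
    n_components = int(mesh.body_count)
    if check_self_intersections and len(mesh.faces) <= max_faces_for_intersection:
        nsi = count_self_intersections(mesh)
    else:
        nsi = 0
    min_edge = float(np.linalg.norm(
        mesh.vertices[mesh.edges_unique[:, 0]] - mesh.vertices[mesh.edges_unique[:, 1]],
        axis=1).min(initial=np.inf)) if len(mesh.edges_unique) else 0.0
    return MeshQCReport(
        watertight=watertight,
        manifold=manifold,
        n_components=n_components,
        n_faces=int(len(mesh.faces)),
        self_intersections=int(nsi),
        min_edge=min_edge,
    )


def decimate(mesh: trimesh.Trimesh, target_faces: int) -> trimesh.Trimesh:
    """Quadric edge-collapse decimation to ``target_faces``.

    Collapses are placed at the quadric-optimal position; boundary edges are
    locked; face normals are prevented from flipping, which preserves the
    topology of closed meshes.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be at least 4 (minimal closed surface)")
    if target_faces >= len(mesh.faces):
        return mesh.copy()
    verts, faces = simplify_mesh_arrays(mesh.vertices, mesh.faces, target_faces)
    if len(faces) > target_faces:
        # threshold schedule exhausted before target: one more aggressive round
        verts, faces = simplify_mesh_arrays(verts, faces, target_faces,
                                            aggressiveness=9.0)
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return out


@njit(cache=True, parallel=True)
def _min_dist_candidates(points, tris, cand, ptr, fallback_all):
    n = points.shape[0]
    dist = np.empty(n)
    for i in prange(n):
        best = np.inf
        p = points[i]
        lo, hi = ptr[i], ptr[i + 1]
        if hi > lo:
            for k in range(lo, hi):
                f = cand[k]
                d2, _, _, _ = _pt_tri_sq(p, tris[f, 0], tris[f, 1], tris[f, 2])
                if d2 < best:
                    best = d2
        else:
            for f in range(tris.shape[0]):
                d2, _, _, _ = _pt_tri_sq(p, tris[f, 0], tris[f, 1], tris[f, 2])
                if d2 < best:
                    best = d2
        dist[i] = np.sqrt(best)
    return dist


def surface_distance(points: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface.

    A vertex KD-tree gives an upper bound per query point; only triangles
    whose centroid can beat that bound are tested exactly, so the result
    equals the brute-force O(V*F) scan.
    """
    points = np.ascontiguousarray(points, dtype=np.float64)
    tris = np.ascontiguousarray(mesh.triangles, dtype=np.float64)
    if len(tris) == 0:
        raise ValueError("empty mesh")
    if len(tris) * len(points) <= 2_000_000:
        return min_dist_to_triangles(points, tris)
    vtree = cKDTree(mesh.vertices)
    centroids = tris.mean(axis=1)
    tri_radius = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(axis=1)
    ctree = cKDTree(centroids)
    rmax = float(tri_radius.max()) + 1e-9
    out = np.empty(len(points))
    chunk = 100_000
    for s in range(0, len(points), chunk):
        pts = points[s:s + chunk]
        upper = vtree.query(pts, workers=-1)[0]
        groups = ctree.query_ball_point(pts, upper + rmax, workers=-1)
        ptr = np.zeros(len(pts) + 1, dtype=np.int64)
        ptr[1:] = np.cumsum([len(g) for g in groups])
        cand = np.concatenate([np.asarray(g, dtype=np.int64) for g in groups]) \
            if ptr[-1] else np.zeros(0, dtype=np.int64)
        out[s:s + chunk] = _min_dist_candidates(pts, tris, cand, ptr, False)
    return out


def hausdorff(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh,
              symmetric: bool = False) -> dict:
    """Hausdorff distance sampled on all vertices.

    One-sided (default): distances from every vertex of ``mesh_a`` to the
    surface of ``mesh_b``. Symmetric: max/mean over both directions. The mean
    is of absolute distances.
    """
    if len(mesh_a.faces) == 0 or len(mesh_b.faces) == 0:
        raise ValueError("empty mesh")
    d_ab = surface_distance(np.asarray(mesh_a.vertices), mesh_b)
    if not symmetric:
        return {"max": float(d_ab.max()), "mean": float(np.abs(d_ab).mean())}
    d_ba = surface_distance(np.asarray(mesh_b.vertices), mesh_a)
    return {
        "max": float(max(d_ab.max(), d_ba.max())),
        "mean": float(max(np.abs(d_ab).mean(), np.abs(d_ba).mean())),
    }


@njit(cache=True)
def _tri_tri_overlap(t1, t2):
    """Do two triangles properly intersect? Conservative segment-plane test:
    intersect each edge of one triangle with the plane/interior of the other."""
    for swap in range(2):
        a = t1 if swap == 0 else t2
        b = t2 if swap == 0 else t1
        # plane of b
        e1 = b[1] - b[0]
        e2 = b[2] - b[0]
        nx = e1[1] * e2[2] - e1[2] * e2[1]
        ny = e1[2] * e2[0] - e1[0] * e2[2]
        nz = e1[0] * e2[1] - e1[1] * e2[0]
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn == 0.0:
            return False
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        d = -(nx * b[0, 0] + ny * b[0, 1] + nz * b[0, 2])
        for i in range(3):
            p = a[i]
            q = a[(i + 1) % 3]
            sp = nx * p[0] + ny * p[1] + nz * p[2] + d
            sq = nx * q[0] + ny * q[1] + nz * q[2] + d
            if sp * sq >= -1e-12:
                continue
            t = sp / (sp - sq)
            if t <= 1e-9 or t >= 1.0 - 1e-9:
                continue
            xx = p[0] + t * (q[0] - p[0])
            xy = p[1] + t * (q[1] - p[1])
            xz = p[2] + t * (q[2] - p[2])
            # barycentric inside-test for x in triangle b
            v0x, v0y, v0z = e1[0], e1[1], e1[2]
            v1x, v1y, v1z = e2[0], e2[1], e2[2]
            v2x, v2y, v2z = xx - b[0, 0], xy - b[0, 1], xz - b[0, 2]
            d00 = v0x * v0x + v0y * v0y + v0z * v0z
            d01 = v0x * v1x + v0y * v1y + v0z * v1z
            d11 = v1x * v1x + v1y * v1y + v1z * v1z
            d20 = v2x * v0x + v2y * v0y + v2z * v0z
            d21 = v2x * v1x + v2y * v1y + v2z * v1z
            den = d00 * d11 - d01 * d01
            if den == 0.0:
                continue
            u = (d11 * d20 - d01 * d21) / den
            v = (d00 * d21 - d01 * d20) / den
            if u > 1e-9 and v > 1e-9 and u + v < 1.0 - 1e-9:
                return True
    return False


@njit(cache=True)
def _count_intersections(tris, faces, cell_of, order, starts, cells):
    """Count intersecting non-adjacent face pairs using a spatial hash."""
    count = 0
    ncells = starts.shape[0] - 1
    for c in range(ncells):
        lo, hi = starts[c], starts[c + 1]
        for ii in range(lo, hi):
            fi = order[ii]
            for jj in range(ii + 1, hi):
                fj = order[jj]
                shared = False
                for u in range(3):
                    for w in range(3):
                        if faces[fi, u] == faces[fj, w]:
                            shared = True
                if shared:
                    continue
                if _tri_tri_overlap(tris[fi], tris[fj]):
                    count += 1
    return count


def count_self_intersections(mesh: trimesh.Trimesh) -> int:
    """Number of properly intersecting non-adjacent triangle pairs (spatial
    hash on triangle centroids; pairs are only tested within a cell, so very
    long sliver triangles may be missed -- adequate as a QC smoke signal)."""
    tris = np.ascontiguousarray(mesh.triangles, dtype=np.float64)
    if len(tris) < 2:
        return 0
    edge = float(np.linalg.norm(
        tris[:, 1] - tris[:, 0], axis=1).mean())
    cell = max(edge * 2.0, 1e-6)
    centroids = tris.mean(axis=1)
    keys = np.floor(centroids / cell).astype(np.int64)
    # hash to linear ids
    _, cell_of = np.unique(keys, axis=0, return_inverse=True)
    order = np.argsort(cell_of, kind="stable").astype(np.int64)
    sorted_cells = cell_of[order]
    boundaries = np.flatnonzero(np.diff(sorted_cells)) + 1
    starts = np.concatenate([[0], boundaries, [len(order)]]).astype(np.int64)
    return int(_count_intersections(
        tris, np.ascontiguousarray(mesh.faces, dtype=np.int64),
        cell_of.astype(np.int64), order, starts, sorted_cells))
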