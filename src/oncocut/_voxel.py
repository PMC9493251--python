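"""Voxel occupancy engine.

Rasterizes watertight triangle meshes into boolean occupancy grids by
z-column ray parity, composes solids with array booleans (the package's
boolean engine for guide assembly), and converts occupancy back to
watertight surfaces via marching cubes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from skimage import measure

__all__ = ["VoxelGrid", "voxelize", "occupancy_to_mesh", "signed_distance_grid"]


@njit(cache=True)
def _rasterize_columns(verts, faces, ox, oy, pitch, nx, ny, max_hits):
    """For every (ix, iy) pixel column record triangle z-crossings.

    Returns (counts[nx, ny], zhits[nx, ny, max_hits]). Column ray origins are
    jittered off the lattice so axis-aligned mesh edges are not hit exactly.
    """
    counts = np.zeros((nx, ny), dtype=np.int32)
    zhits = np.empty((nx, ny, max_hits))
    jx = 0.147318 * pitch
    jy = 0.059263 * pitch
    for f in range(faces.shape[0]):
        a = verts[faces[f, 0]]
        b = verts[faces[f, 1]]
        c = verts[faces[f, 2]]
        d = (b[1] - a[1]) * (c[0] - a[0]) - (b[0] - a[0]) * (c[1] - a[1])
        if d == 0.0:
            continue
        xmin = min(a[0], min(b[0], c[0]))
        xmax = max(a[0], max(b[0], c[0]))
        ymin = min(a[1], min(b[1], c[1]))
        ymax = max(a[1], max(b[1], c[1]))
        i0 = max(0, int(np.ceil((xmin - ox - jx) / pitch)))
        i1 = min(nx - 1, int(np.floor((xmax - ox - jx) / pitch)))
        j0 = max(0, int(np.ceil((ymin - oy - jy) / pitch)))
        j1 = min(ny - 1, int(np.floor((ymax - oy - jy) / pitch)))
        for i in range(i0, i1 + 1):
            px = ox + i * pitch + jx
            for j in range(j0, j1 + 1):
                py = oy + j * pitch + jy
                u = ((py - a[1]) * (c[0] - a[0]) - (px - a[0]) * (c[1] - a[1])) / d
                v = ((b[0] - a[0]) * (py - a[1]) - (b[1] - a[1]) * (px - a[0])) / -d
                if u < 0.0 or v < 0.0 or u + v > 1.0:
                    continue
                z = a[2] + u * (b[2] - a[2]) + v * (c[2] - a[2])
                k = counts[i, j]
                if k < max_hits:
                    zhits[i, j, k] = z
                    counts[i, j] = k + 1
    return counts, zhits


@njit(cache=True)
def _fill_parity(counts, zhits, oz, pitch, nz, occ):
    nx, ny = counts.shape
    for i in range(nx):
        for j in range(ny):
            m = counts[i, j]
            if m < 2:
                continue
            zs = np.sort(zhits[i, j, :m])
            for p in range(0, m - 1, 2):
                z0 = zs[p]
                z1 = zs[p + 1]
                k0 = max(0, int(np.ceil((z0 - oz) / pitch)))
                k1 = min(nz - 1, int(np.floor((z1 - oz) / pitch)))
                for k in range(k0, k1 + 1):
                    occ[i, j, k] = True


@dataclass
class VoxelGrid:
    """Boolean occupancy on a regular axis-aligned grid (world mm)."""

    occ: np.ndarray  # bool, shape (nx, ny, nz), voxel value at center
    origin: np.ndarray  # world position of voxel (0, 0, 0) center
    pitch: float

    @classmethod
    def empty(cls, lo, hi, pitch: float, pad: int = 2) -> "VoxelGrid":
        lo = np.asarray(lo, dtype=float) - pad * pitch
        hi = np.asarray(hi, dtype=float) + pad * pitch
        shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 1)
        return cls(np.zeros(tuple(shape), dtype=bool), lo, float(pitch))

    @property
    def shape(self):
        return self.occ.shape

    def centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.pitch * np.arange(self.occ.shape[axis])

    def world_grid(self):
        """Meshgrid of voxel-center coordinates (sparse broadcastable)."""
        xs = self.centers_axis(0)[:, None, None]
        ys = self.centers_axis(1)[None, :, None]
        zs = self.centers_axis(2)[None, None, :]
        return xs, ys, zs

    def add_mesh(self, mesh) -> None:
        self.occ |= voxelize(mesh, self.origin, self.pitch, self.occ.shape)

    def subtract_mesh(self, mesh) -> None:
        self.occ &= ~voxelize(mesh, self.origin, self.pitch, self.occ.shape)

    def add_mask(self, mask: np.ndarray) -> None:
        self.occ |= mask

    def subtract_mask(self, mask: np.ndarray) -> None:
        self.occ &= ~mask

    def cylinder_mask(self, point, axis, radius, half_length=np.inf) -> np.ndarray:
        """Occupancy of an (optionally finite) cylinder around a line."""
        point = np.asarray(point, dtype=float)
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        xs, ys, zs = self.world_grid()
        dx = xs - point[0]
        dy = ys - point[1]
        dz = zs - point[2]
        t = dx * axis[0] + dy * axis[1] + dz * axis[2]
        r2 = (dx - t * axis[0]) ** 2 + (dy - t * axis[1]) ** 2 + (dz - t * axis[2]) ** 2
        mask = r2 <= radius * radius
        if np.isfinite(half_length):
            mask &= np.abs(t) <= half_length
        return mask

    def add_sphere(self, center, radius) -> None:
        """Emboss a small sphere (cropped local update)."""
        center = np.asarray(center, dtype=float)
        lo = np.maximum(((center - radius - self.origin) / self.pitch).astype(int), 0)
        hi = np.minimum(((center + radius - self.origin) / self.pitch).astype(int) + 2,
                        self.shape)
        if (hi <= lo).any():
            return
        xs = self.origin[0] + self.pitch * np.arange(lo[0], hi[0])[:, None, None]
        ys = self.origin[1] + self.pitch * np.arange(lo[1], hi[1])[None, :, None]
        zs = self.origin[2] + self.pitch * np.arange(lo[2], hi[2])[None, None, :]
        r2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2
        self.occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= r2 <= radius * radius

    def halfspace_mask(self, point, normal) -> np.ndarray:
        """Voxels with (x - point) . normal > 0."""
        point = np.asarray(point, dtype=float)
        normal = np.asarray(normal, dtype=float)
        xs, ys, zs = self.world_grid()
        s = (
            (xs - point[0]) * normal[0]
            + (ys - point[1]) * normal[1]
            + (zs - point[2]) * normal[2]
        )
        return s > 0.0

    def volume(self) -> float:
        return float(self.occ.sum()) * self.pitch**3

    def to_mesh(self, smooth: bool = False):
        return occupancy_to_mesh(self.occ, self.origin, self.pitch, smooth=smooth)


def voxelize(mesh, origin, pitch: float, shape) -> np.ndarray:
    """Boolean occupancy of a watertight mesh sampled at voxel centers."""
    verts = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    counts, zhits = _rasterize_columns(
        verts, faces, origin[0], origin[1], pitch, nx, ny, 64
    )
    occ = np.zeros((nx, ny, nz), dtype=bool)
    _fill_parity(counts, zhits, origin[2], pitch, nz, occ)
    return occ


def occupancy_to_mesh(occ: np.ndarray, origin, pitch: float, smooth: bool = False):
    """Marching-cubes surface of a boolean grid; watertight by construction."""
    import trimesh

    if not occ.any():
        raise ValueError("empty occupancy grid")
    field = np.pad(occ.astype(np.float32), 1)
    if smooth:
        field = ndimage.gaussian_filter(field, sigma=0.9)
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5)
    verts = (verts - 1.0) * pitch + np.asarray(origin, dtype=float)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()
    return mesh


def signed_distance_grid(occ: np.ndarray, pitch: float) -> np.ndarray:
    """Approximate signed distance (mm), negative inside, from occupancy."""
    dout = ndimage.distance_transform_edt(~occ) * pitch
    din = ndimage.distance_transform_edt(occ) * pitch
    return dout - din
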