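"""Seeded synthetic pelvis-like phantoms: bone + tumor meshes and
pseudo-CT / pseudo-MR volumes.

The bone is a stylized hemipelvis assembled from implicit primitives that
reproduce the topological traps of the real pelvis -- a thin iliac-wing
plate with a free crest edge, an acetabular cup shell, an ischiopubic ring
whose central opening plays the obturator foramen, and a sacral block
pierced by foramen-like holes. Four implantable tumors cover the Enneking
resection zones (I iliac crest, II acetabulum, III ischium, I+IV
sacroiliac). Meshes come from marching cubes over the signed field, so
every emitted body is watertight; identical (case_id, seed, params)
reproduce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volumes import Volume

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "GroundTruthTransform",
    "CASE_IDS",
    "make_case",
    "synth_ct",
    "synth_mr",
    "dense_bone",
]

CASE_IDS = (
    "zone_I_iliac_crest",
    "zone_II_acetabulum",
    "zone_III_ischium",
    "zone_I_IV_sacroiliac",
)

# world-domain corners of the phantom (mm, LPS)
_DOMAIN_LO = np.array([0.0, 35.0, -5.0])
_DOMAIN_HI = np.array([155.0, 105.0, 150.0])

# intensity levels: CT orders bone >> tumor >> background, MR inverts
CT_LEVELS = {"background": 0.0, "tumor": 400.0, "bone": 1200.0}
MR_LEVELS = {"background": 60.0, "bone": 250.0, "tumor": 900.0}
# per-tissue amplitude of the shared trabecular-like texture. The texture is
# anatomy: it deforms with the tissue, so the CT-MR registration problem is
# well posed everywhere (piecewise-constant tissue would leave motion along
# smooth surfaces unobservable).
CT_TEXTURE = {"bone": 90.0, "tumor": 60.0}
MR_TEXTURE = {"bone": 70.0, "tumor": 60.0}


@dataclass
class PhantomParams:
    bone_extent: tuple = (155.0, 70.0, 155.0)
    cortical_thickness: float = 6.0
    tumor_radius: tuple = (16.0, 13.0, 10.0)
    ct_spacing: tuple = (1.0, 1.0, 1.0)
    mr_spacing: tuple = (1.0, 1.0, 1.5)
    noise_sd: float = 20.0
    texture_amplitude: float = 1.0  # scales the trabecular-like texture
    deformation_amplitude: float = 3.0
    mesh_pitch: float = 1.0
    tumor_mesh_pitch: float = 0.8

    def __post_init__(self):
        for name in ("bone_extent", "tumor_radius", "ct_spacing", "mr_spacing"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if not (1.0 <= self.mr_spacing[2] <= 2.0):
            raise ValueError("MR slice spacing must lie in [1, 2] mm")


# ---------------------------------------------------------------------------
# implicit primitives (vectorized over an (N, 3) point array)

def _rounded_box(p, center, half, r):
    q = np.abs(p - center) - (np.asarray(half) - r)
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(q.max(axis=-1), 0.0)
    return outside + inside - r


def _cup_shell(p, center, radius, thickness, opening, keep_below):
    d = np.linalg.norm(p - center, axis=-1)
    shell = np.abs(d - radius) - 0.5 * thickness
    s = (p - center) @ np.asarray(opening)
    return np.maximum(shell, -(s + keep_below))


def _torus_y(p, center, major, minor):
    dx = p[..., 0] - center[0]
    dz = p[..., 2] - center[2]
    q0 = np.sqrt(dx * dx + dz * dz) - major
    q1 = p[..., 1] - center[1]
    return np.sqrt(q0 * q0 + q1 * q1) - minor


def _capsule(p, a, b, r):
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[..., None] * ab), axis=-1) - r


def _cyl_hole_y(p, x0, z0, r):
    return np.sqrt((p[..., 0] - x0) ** 2 + (p[..., 2] - z0) ** 2) - r


def _ellipsoid(p, center, radii, rotation):
    """Approximate signed distance of a rotated ellipsoid (sign-exact)."""
    q = (p - center) @ rotation  # into the ellipsoid frame
    radii = np.asarray(radii)
    k0 = np.linalg.norm(q / radii, axis=-1)
    k1 = np.linalg.norm(q / radii**2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(k1 > 0, k0 * (k0 - 1.0) / k1, -radii.min())
    return d


_PRESETS = {
    "zone_I_iliac_crest": {
        "tumor_center": (95.0, 70.0, 133.0),
        "approach": (0.0, 0.0, 1.0),
        "n_segments": 2,
        "clip_point": (68.0, 70.0, 130.0),
    },
    "zone_II_acetabulum": {
        "tumor_center": (120.0, 84.0, 76.0),
        "approach": (0.0, 0.55, 0.835),
        "n_segments": 3,
        "clip_point": None,
    },
    "zone_III_ischium": {
        "tumor_center": (111.0, 70.0, 15.0),
        "approach": (0.7, 0.0, -0.714),
        "n_segments": 2,
        "clip_point": None,
    },
    "zone_I_IV_sacroiliac": {
        "tumor_center": (57.0, 70.0, 108.0),
        "approach": (0.0, 0.0, 1.0),
        "n_segments": 4,
        "clip_point": None,
    },
}


def _base_bone_sdf(p):
    parts = [
        # iliac wing plate (thin, free crest edge at z = 135)
        _rounded_box(p, np.array([95.0, 70.0, 105.0]), np.array([40.0, 3.0, 30.0]), 3.0),
        # acetabular cup shell
        _cup_shell(p, np.array([120.0, 70.0, 55.0]), 26.0, 6.0,
                   np.array([0.0, 1.0, 0.0]), 5.0),
        # ischiopubic ring; the torus opening is the obturator-like foramen
        _torus_y(p, np.array([95.0, 70.0, 30.0]), 22.0, 7.0),
        # connectors keeping the bone a single solid
        _capsule(p, (95.0, 70.0, 75.0), (118.0, 70.0, 76.0), 7.0),
        _capsule(p, (120.0, 70.0, 32.0), (113.0, 70.0, 30.0), 7.0),
        _capsule(p, (52.0, 70.0, 100.0), (72.0, 70.0, 105.0), 7.0),
    ]
    # sacral block with two foramen-like through-holes
    block = _rounded_box(p, np.array([30.0, 70.0, 90.0]), np.array([25.0, 20.0, 35.0]), 4.0)
    for z0 in (75.0, 105.0):
        block = np.maximum(block, -_cyl_hole_y(p, 30.0, z0, 4.0))
    parts.append(block)
    return np.minimum.reduce(parts)


@dataclass
class GroundTruthTransform:
    """Smooth synthetic deformation with a known exact inverse.

    The moving (MR) frame relates to the fixed (CT) frame through a cubic
    B-spline interpolated displacement field v on a coarse control grid:
    a moving point y corresponds to fixed point x = y + v(y). The
    fixed-to-moving map (the resampling convention shared with
    :class:`~oncocut.volumes.DeformableTransform`) is obtained by
    fixed-point iteration; amplitudes are small against the control
    spacing, so the field is a contraction and inversion converges.
    """

    control_origin: np.ndarray
    control_spacing: float
    control_field: np.ndarray  # (nx, ny, nz, 3) mm displacements
    fixed_reference: Volume | None = None

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - self.control_origin) / self.control_spacing
        out = np.empty_like(pts)
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.control_field[..., c], idx.T, order=3, mode="nearest")
        return out

    def map_moving_to_fixed(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts + self.displacement_at(pts)

    def map_fixed_to_moving(self, points: np.ndarray, iters: int = 15) -> np.ndarray:
        x = np.atleast_2d(np.asarray(points, dtype=float))
        y = x.copy()
        for _ in range(iters):
            y = x - self.displacement_at(y)
        return y

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Fixed-to-moving displacement (matches DeformableTransform)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.map_fixed_to_moving(pts) - pts


@dataclass
class PhantomCase:
    case_id: str
    seed: int
    params: PhantomParams
    bone: trimesh.Trimesh
    tumor: trimesh.Trimesh
    bone_sdf: Callable = field(repr=False, default=None)
    tumor_sdf: Callable = field(repr=False, default=None)
    texture: Callable = field(repr=False, default=None)
    approach: np.ndarray = None
    tumor_center: np.ndarray = None
    n_segments: int = 2
    clip_point: np.ndarray | None = None
    domain: tuple = (_DOMAIN_LO, _DOMAIN_HI)

    def plane_points(self, offset: float = 60.0, span: float = 40.0):
        """Three points defining the approach plane above the tumor, with the
        right-hand-rule normal equal to the approach direction."""
        a = self.approach
        o = self.tumor_center + offset * a
        u = np.cross(a, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(a, [0.0, 1.0, 0.0])
        u = u / np.linalg.norm(u)
        v = np.cross(a, u)  # cross(u, v) = -a? ensure cross(u,v)=a
        if np.dot(np.cross(u, v), a) < 0:
            v = -v
        return o, o + span * u, o + span * v


def _mesh_from_sdf(sdf, lo, hi, pitch) -> trimesh.Trimesh:
    # sample off-lattice so flat primitive faces never hit exact zeros
    lo = np.asarray(lo, dtype=float) - 0.31258716 * pitch
    axes = [np.arange(lo[a], hi[a] + pitch, pitch) for a in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    values = sdf(grid.reshape(-1, 3)).reshape(grid.shape[:-1])
    verts, faces, _, _ = measure.marching_cubes(values, level=0.0)
    verts = verts * pitch + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    mesh.fix_normals()
    return mesh


def make_case(case_id: str, seed: int, params: PhantomParams | None = None) -> PhantomCase:
    """Generate one phantom preset: watertight bone and tumor meshes plus the
    implicit fields they were extracted from."""
    if case_id not in CASE_IDS:
        raise ValueError(f"invalid case_id {case_id!r}; choose from {CASE_IDS}")
    if seed < 0:
        raise ValueError("seed must be >= 0")
    params = params or PhantomParams()
    preset = _PRESETS[case_id]

    rng = np.random.default_rng([int(seed), 11, list(CASE_IDS).index(case_id)])
    jitter = rng.uniform(-1.5, 1.5, 3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, 12.0))
    rotation = trimesh.transformations.rotation_matrix(angle, axis)[:3, :3]

    center = np.asarray(preset["tumor_center"]) + jitter
    radii = np.asarray(params.tumor_radius)

    def tumor_sdf(p):
        return _ellipsoid(np.asarray(p, dtype=float), center, radii, rotation)

    # smooth trabecular-like texture: a fixed sum of random-direction cosine
    # waves (wavelengths 8-16 mm), evaluable at any anatomical point
    rng_t = np.random.default_rng([int(seed), 41])
    k = 12
    freqs = rng_t.normal(size=(k, 3))
    freqs *= (2 * np.pi / rng_t.uniform(8.0, 16.0, k)[:, None]) \
        / np.linalg.norm(freqs, axis=1)[:, None]
    phases = rng_t.uniform(0, 2 * np.pi, k)
    amps = rng_t.uniform(0.5, 1.0, k)
    amps /= np.sqrt((amps**2).sum() / 2.0)  # unit RMS

    def texture(p):
        return np.sum(amps[None, :] * np.cos(np.asarray(p, dtype=float)
                                             @ freqs.T + phases[None, :]), axis=-1)

    capsule = params.cortical_thickness / 3.0

    def bone_sdf(p):
        p = np.asarray(p, dtype=float)
        # the implanted lesion bulges the bone: union with a thin capsule
        return np.minimum(_base_bone_sdf(p), tumor_sdf(p) - capsule)

    bone = _mesh_from_sdf(bone_sdf, _DOMAIN_LO, _DOMAIN_HI, params.mesh_pitch)
    pad = radii.max() + 5.0
    tumor = _mesh_from_sdf(
        tumor_sdf, center - pad, center + pad, params.tumor_mesh_pitch)

    approach = np.asarray(preset["approach"], dtype=float)
    approach /= np.linalg.norm(approach)
    return PhantomCase(
        case_id=case_id, seed=seed, params=params, bone=bone, tumor=tumor,
        bone_sdf=bone_sdf, tumor_sdf=tumor_sdf, texture=texture,
        approach=approach,
        tumor_center=center, n_segments=preset["n_segments"],
        clip_point=None if preset["clip_point"] is None
        else np.asarray(preset["clip_point"], dtype=float),
    )


def _labels_at(case: PhantomCase, points: np.ndarray) -> np.ndarray:
    """0 background, 1 bone, 2 tumor; tumor wins inside the lesion."""
    lab = np.zeros(points.shape[0], dtype=np.int32)
    lab[case.bone_sdf(points) < 0] = 1
    lab[case.tumor_sdf(points) < 0] = 2
    return lab


def _grid_points(origin, spacing, shape):
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


def synth_ct(case: PhantomCase) -> Volume:
    """Pseudo-CT of the case: bone brightest, then tumor, then background,
    plus additive Gaussian noise of sd ``params.noise_sd``."""
    params = case.params
    spacing = np.asarray(params.ct_spacing, dtype=float)
    lo, hi = case.domain
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    pts = _grid_points(lo, spacing, shape)
    lab = _labels_at(case, pts)
    data = np.full(len(pts), CT_LEVELS["background"], dtype=np.float32)
    data[lab == 1] = CT_LEVELS["bone"]
    data[lab == 2] = CT_LEVELS["tumor"]
    if params.texture_amplitude > 0:
        t = case.texture(pts).astype(np.float32)
        a = params.texture_amplitude
        data[lab == 1] += a * CT_TEXTURE["bone"] * t[lab == 1]
        data[lab == 2] += a * CT_TEXTURE["tumor"] * t[lab == 2]
    data = data.reshape(shape)
    if params.noise_sd > 0:
        rng = np.random.default_rng([int(case.seed), 17])
        data = data + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)
    return Volume(data=data, spacing=spacing, origin=lo.copy())


def synth_mr(case: PhantomCase, control_spacing: float = 24.0):
    """Pseudo-MR (tumor brightest) seen through a smooth random deformation
    of amplitude ``params.deformation_amplitude``; the ground-truth
    transform is returned alongside.

    The MR intensity at moving-frame point y is the anatomy evaluated at
    the fixed-frame point y + v(y), sampled analytically from the implicit
    fields (no interpolation blur).
    """
    params = case.params
    spacing = np.asarray(params.mr_spacing, dtype=float)
    lo, hi = case.domain
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)

    margin = 2.0 * control_spacing
    c_lo = lo - margin
    c_shape = tuple(np.ceil((hi + margin - c_lo) / control_spacing).astype(int) + 1)
    rng = np.random.default_rng([int(case.seed), 29])
    fieldv = rng.normal(0.0, 1.0, c_shape + (3,))
    amp = params.deformation_amplitude
    norms = np.linalg.norm(fieldv, axis=-1)
    fieldv *= 0.0 if amp == 0 else (amp / norms.max())
    gt = GroundTruthTransform(
        control_origin=c_lo, control_spacing=control_spacing,
        control_field=fieldv)

    pts = _grid_points(lo, spacing, shape)
    anat_pts = gt.map_moving_to_fixed(pts)
    lab = _labels_at(case, anat_pts)
    data = np.full(len(pts), MR_LEVELS["background"], dtype=np.float32)
    data[lab == 1] = MR_LEVELS["bone"]
    data[lab == 2] = MR_LEVELS["tumor"]
    if params.texture_amplitude > 0:
        t = case.texture(anat_pts).astype(np.float32)
        a = params.texture_amplitude
        data[lab == 1] += a * MR_TEXTURE["bone"] * t[lab == 1]
        data[lab == 2] += a * MR_TEXTURE["tumor"] * t[lab == 2]
    data = data.reshape(shape)
    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd, shape).astype(np.float32)
    vol = Volume(data=data, spacing=spacing, origin=lo.copy())
    return vol, gt


def dense_bone(case: PhantomCase, min_faces: int = 2_000_001) -> trimesh.Trimesh:
    """Oversampled copy of the bone (midpoint subdivision) for decimation
    work, mimicking the face counts of raw clinical surface exports."""
    verts = np.asarray(case.bone.vertices)
    faces = np.asarray(case.bone.faces)
    while len(faces) < min_faces:
        verts, faces = trimesh.remesh.subdivide(verts, faces)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)
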