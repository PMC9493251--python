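"""Volume processing: I/O, deformable CT-MR registration, marker-based
watershed segmentation and iso-surface extraction.

Conventions
-----------
World frame is right-handed LPS in mm, shared with all meshes. A
:class:`Volume` stores its scalar grid indexed ``[i, j, k]`` with the
index-to-world map ``world = origin + direction @ (spacing * index)``;
values live at voxel centers. SimpleITK backs file I/O, resampling and the
multi-resolution B-spline registration; scikit-image backs watershed and
marching cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
import trimesh
from scipy import ndimage
from skimage import measure, segmentation

__all__ = [
    "Volume",
    "LabelVolume",
    "DeformableTransform",
    "read_volume",
    "write_volume",
    "register",
    "segment_watershed",
    "auto_markers",
    "band_markers",
    "read_markers",
    "write_markers",
    "apply_transform",
    "extract_surface",
    "dice",
]

BACKGROUND, BONE, TUMOR = 0, 1, 2
_MARKER_BACKGROUND = 3  # watershed markers cannot use label 0


@dataclass
class Volume:
    """3D scalar grid with world-space geometry."""

    data: np.ndarray  # shape (nx, ny, nz)
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if (self.spacing <= 0).any():
            raise ValueError("spacing must be positive")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction must be orthonormal")

    @property
    def shape(self):
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx * self.spacing) @ self.direction.T

    def voxel_centers(self):
        """Broadcastable world coordinate arrays (identity-direction grids)."""
        if not np.allclose(self.direction, np.eye(3)):
            raise ValueError("voxel_centers requires identity direction")
        ax = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
              for a in range(3)]
        return ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :]

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        data = sitk.GetArrayFromImage(img).T  # sitk arrays are [z, y, x]
        return cls(
            data=np.ascontiguousarray(data),
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
        )


@dataclass
class LabelVolume(Volume):
    """Integer grid sharing its geometry with the source volume.

    Legend: 0 background, 1 bone, 2 tumor.
    """

    legend: dict = field(default_factory=lambda: {0: "background", 1: "bone", 2: "tumor"})

    def counts(self) -> dict:
        ids, n = np.unique(self.data, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, n)}


_SUPPORTED = (".nrrd", ".nhdr", ".nii", ".nii.gz", ".mha", ".mhd")


def read_volume(path) -> Volume:
    """Read an NRRD/NIfTI volume, normalized to the canonical LPS axis order
    (world coordinates of every voxel are unchanged by the reorientation)."""
    p = str(path)
    if not any(p.endswith(s) for s in _SUPPORTED):
        raise ValueError(f"unsupported volume format: {p}")
    img = sitk.ReadImage(p)
    img = sitk.DICOMOrient(img, "LPS")
    return Volume.from_sitk(img)


def write_volume(volume: Volume, path) -> None:
    p = str(path)
    if not any(p.endswith(s) for s in _SUPPORTED):
        raise ValueError(f"unsupported volume format: {p}")
    sitk.WriteImage(volume.to_sitk(), p)


class DeformableTransform:
    """Free-form deformation mapping fixed-frame points to the moving frame
    (the resampling convention). The inverse map is found numerically by
    fixed-point iteration on the displacement field."""

    def __init__(self, transform: sitk.Transform, fixed_reference: Volume | None = None,
                 final_metric: float | None = None):
        self.transform = transform
        self.fixed_reference = fixed_reference
        self.final_metric = final_metric

    def map_fixed_to_moving(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.array([self.transform.TransformPoint(tuple(p)) for p in pts])

    def displacement(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.map_fixed_to_moving(pts) - pts

    def map_moving_to_fixed(self, points: np.ndarray, iters: int = 20) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x = pts.copy()
        for _ in range(iters):
            x = pts - self.displacement(x)
        return x


def register(fixed_ct: Volume, moving_mr: Volume, control_spacing: float = 25.0,
             levels: int = 3, sampling: float = 0.2, seed: int = 42,
             iterations: int = 80) -> DeformableTransform:
    """Multi-resolution free-form (B-spline) registration maximizing Mattes
    mutual information -- multimodality-safe. Deterministic for a fixed
    metric-sampling seed.

    Raises ``RuntimeError`` if the optimizer fails to improve the metric
    (reported with the final metric value).
    """
    f = sitk.Cast(fixed_ct.to_sitk(), sitk.sitkFloat32)
    m = sitk.Cast(moving_mr.to_sitk(), sitk.sitkFloat32)

    size = np.array(f.GetSize()) * np.array(f.GetSpacing())
    mov_size = np.array(m.GetSize()) * np.array(m.GetSpacing())
    overlap = np.minimum(np.array(f.GetOrigin()) + size,
                         np.array(m.GetOrigin()) + mov_size) - \
        np.maximum(np.array(f.GetOrigin()), np.array(m.GetOrigin()))
    if (overlap <= 0).any():
        raise ValueError("fixed and moving volumes do not overlap")

    coarse_mesh = np.maximum(
        (size / (control_spacing * 2 ** (levels - 1))).astype(int), 1)
    tx = sitk.BSplineTransformInitializer(f, [int(s) for s in coarse_mesh])

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=40)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(sampling, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGS2(numberOfIterations=iterations)
    reg.SetInitialTransformAsBSpline(
        tx, inPlace=True, scaleFactors=[2 ** k for k in range(levels)])
    shrink = [2 ** (levels - 1 - k) for k in range(levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()

    initial = _metric_only(f, m, tx, sampling, seed)
    out = reg.Execute(f, m)
    final = reg.GetMetricValue()
    if final > initial + 1e-9:
        raise RuntimeError(
            f"registration did not converge (initial metric {initial:.5f}, "
            f"final {final:.5f})")
    return DeformableTransform(out, fixed_reference=fixed_ct, final_metric=final)


def _metric_only(f, m, tx, sampling, seed) -> float:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=40)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(sampling, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    return reg.MetricEvaluate(f, m)


def auto_markers(volume: Volume, structure_label: int, percentile: float | None = None,
                 erode_iters: int = 2, markers: np.ndarray | None = None) -> np.ndarray:
    """Automatic watershed initialization: a high-intensity percentile
    threshold eroded to confident interior seeds, volume border as the
    background seed. The default percentile reflects the expected volume
    fraction of the brightest structure (bone on CT ~ a tenth of the field
    of view; tumor on MR well under one percent)."""
    data = volume.data
    out = np.zeros(data.shape, dtype=np.int32) if markers is None else markers
    if percentile is None:
        percentile = 99.5 if structure_label == TUMOR else 95.0
    thr = np.percentile(data, percentile)
    seed = ndimage.binary_erosion(data > thr, iterations=erode_iters)
    out[seed] = structure_label
    # background seeds: the volume border plus confidently dark voxels (the
    # latter let the background basin reach foramen interiors)
    border = np.zeros(data.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    dark = ndimage.binary_erosion(
        data < np.percentile(data, 60.0), iterations=3)
    out[(border | dark) & (out == 0)] = _MARKER_BACKGROUND
    return out


def write_markers(markers: np.ndarray, path) -> None:
    """Persist watershed seeds as a sparse voxel list (CSV: i,j,k,label)."""
    idx = np.argwhere(markers > 0)
    lab = markers[markers > 0]
    table = np.column_stack([idx, lab]).astype(int)
    np.savetxt(path, table, fmt="%d", delimiter=",", header="i,j,k,label",
               comments="")


def read_markers(path, shape) -> np.ndarray:
    """Load a sparse (i,j,k,label) CSV seed list onto a grid of ``shape``."""
    table = np.loadtxt(path, delimiter=",", skiprows=1, dtype=int, ndmin=2)
    out = np.zeros(shape, dtype=np.int32)
    if table.size:
        out[table[:, 0], table[:, 1], table[:, 2]] = table[:, 3]
    return out


def band_markers(volume: Volume, structure_label: int, low: float, high: float,
                 erode_iters: int = 2,
                 markers: np.ndarray | None = None) -> np.ndarray:
    """Seed a structure of intermediate intensity (e.g. the tumor on a
    mono-modal CT) from an intensity band, eroded to confident voxels."""
    data = volume.data
    out = np.zeros(data.shape, dtype=np.int32) if markers is None else markers
    seed = ndimage.binary_erosion((data > low) & (data < high),
                                  iterations=erode_iters)
    out[seed & (out == 0)] = structure_label
    return out


def segment_watershed(volume: Volume, markers: np.ndarray,
                      gradient_sigma: float = 0.7) -> LabelVolume:
    """Marker-based watershed on the gradient magnitude of the volume.

    ``markers`` is an integer seed grid (1 bone, 2 tumor, 3 background;
    0 = unlabeled). Every voxel ends up labeled; regions grow from their
    markers along intensity-gradient basins.
    """
    markers = np.asarray(markers)
    if markers.shape != volume.shape:
        raise ValueError("marker grid shape must match the volume")
    if not (markers == _MARKER_BACKGROUND).any():
        raise ValueError("missing background marker")
    if (markers > 0).all():
        labels = markers.copy()
    else:
        grad = ndimage.gaussian_gradient_magnitude(
            volume.data.astype(np.float32), sigma=gradient_sigma)
        labels = segmentation.watershed(grad, markers.astype(np.int32))
    labels = np.where(labels == _MARKER_BACKGROUND, BACKGROUND, labels)
    return LabelVolume(
        data=labels.astype(np.int32), spacing=volume.spacing,
        origin=volume.origin, direction=volume.direction)


def apply_transform(obj, transform) -> "LabelVolume | trimesh.Trimesh":
    """Express a moving-frame object in the fixed (CT) world frame.

    Label volumes are resampled onto the transform's fixed reference grid
    (nearest neighbor); meshes have their vertices mapped through the
    inverse (moving-to-fixed) point map.
    """
    if isinstance(obj, trimesh.Trimesh):
        verts = transform.map_moving_to_fixed(np.asarray(obj.vertices))
        return trimesh.Trimesh(vertices=verts, faces=obj.faces.copy(), process=False)
    if isinstance(obj, LabelVolume):
        ref = transform.fixed_reference
        if ref is None:
            raise ValueError("transform has no fixed reference geometry")
        moving = obj.to_sitk()
        out = _resample_labels(moving, ref, transform)
        return LabelVolume(
            data=out, spacing=ref.spacing, origin=ref.origin,
            direction=ref.direction)
    raise TypeError(f"cannot transform {type(obj)!r}")


def _resample_labels(moving: sitk.Image, ref: Volume, transform) -> np.ndarray:
    if isinstance(transform, DeformableTransform):
        tx = transform.transform
        refimg = ref.to_sitk()
        res = sitk.Resample(moving, refimg, tx, sitk.sitkNearestNeighbor, 0.0)
        return sitk.GetArrayFromImage(res).T.astype(np.int32)
    # generic point-map transform (e.g. a phantom ground-truth field):
    xs, ys, zs = ref.voxel_centers()
    pts = np.stack(np.broadcast_arrays(xs, ys, zs), axis=-1).reshape(-1, 3)
    mapped = transform.map_fixed_to_moving(pts)
    vol = Volume.from_sitk(moving)
    idx = (mapped - vol.origin) / vol.spacing
    out = ndimage.map_coordinates(
        vol.data.astype(np.float32), idx.T, order=0, mode="constant", cval=0.0)
    return out.reshape(ref.shape).astype(np.int32)


def extract_surface(labels: LabelVolume, label_id: int,
                    smooth_iters: int = 0, min_component_fraction: float = 0.01
                    ) -> trimesh.Trimesh:
    """Iso-surface of a binary label mask at its 0.5 boundary, in world mm.

    Components smaller than ``min_component_fraction`` of the largest (by
    face count) are dropped; optional light Taubin smoothing (volume
    preserving) with ``smooth_iters`` iterations.
    """
    mask = labels.data == label_id
    if not mask.any():
        raise ValueError(f"label {label_id} not present")
    field_ = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        field_, level=0.5, spacing=tuple(labels.spacing))
    verts = verts - labels.spacing  # remove padding shift
    verts = labels.origin + verts @ labels.direction.T
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        biggest = max(len(p.faces) for p in parts)
        keep = [p for p in parts if len(p.faces) >= min_component_fraction * biggest]
        mesh = trimesh.util.concatenate(keep)
    if smooth_iters > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=smooth_iters)
    mesh.fix_normals()
    return mesh


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
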