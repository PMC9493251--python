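import numpy as np
import pytest
import SimpleITK as sitk
import trimesh

from oncocut import meshproc, phantom, volumes
from oncocut.phantom import _grid_points, _labels_at


@pytest.fixture()
def small_volume():
    rng = np.random.default_rng(0)
    return volumes.Volume(rng.random((20, 25, 18)).astype(np.float32),
                          spacing=(1.0, 1.0, 2.0), origin=(3.0, -4.0, 7.0))


@pytest.mark.parametrize("ext", [".nrrd", ".nii.gz"])
def test_roundtrip_preserves_grid_and_geometry(tmp_path, small_volume, ext):
    p = tmp_path / f"v{ext}"
    volumes.write_volume(small_volume, p)
    back = volumes.read_volume(p)
    np.testing.assert_allclose(back.data, small_volume.data, atol=1e-6)
    np.testing.assert_allclose(back.spacing, small_volume.spacing, atol=1e-6)
    np.testing.assert_allclose(back.origin, small_volume.origin, atol=1e-6)
    np.testing.assert_allclose(back.direction, np.eye(3), atol=1e-6)


def test_unsupported_format_rejected(tmp_path, small_volume):
    with pytest.raises(ValueError):
        volumes.write_volume(small_volume, tmp_path / "v.xyz")


def test_permuted_axes_normalized_world_invariant(tmp_path, small_volume):
    img = small_volume.to_sitk()
    perm = sitk.PermuteAxes(img, [2, 0, 1])
    p = tmp_path / "perm.nrrd"
    sitk.WriteImage(perm, p.as_posix())
    back = volumes.read_volume(p)
    np.testing.assert_allclose(back.direction, np.eye(3), atol=1e-6)
    rng = np.random.default_rng(1)
    for _ in range(10):
        idx = rng.integers(0, small_volume.shape)
        world = small_volume.index_to_world(idx)
        idx2 = np.round((world - back.origin) / back.spacing).astype(int)
        assert np.isclose(back.data[tuple(idx2)],
                          small_volume.data[tuple(idx)])


def test_register_identity_is_near_identity(zone1_case):
    ct = phantom.synth_ct(zone1_case)
    # few iterations and coarse sampling: on identical images the optimizer
    # only has to not drift away from the identity
    tx = volumes.register(ct, ct, iterations=10, levels=2, sampling=0.1)
    pts = np.asarray(zone1_case.bone.vertices)[::3000]
    disp = np.linalg.norm(tx.displacement(pts), axis=1)
    assert disp.mean() < 0.1 * ct.spacing.max()


def test_register_recovers_translation(zone1_case):
    ct = phantom.synth_ct(zone1_case)
    moved = volumes.Volume(ct.data.copy(), ct.spacing,
                           ct.origin + np.array([5.0, 0.0, 0.0]), ct.direction)
    tx = volumes.register(ct, moved, iterations=60)
    pts = np.asarray(zone1_case.bone.vertices)[::3000]
    err = np.linalg.norm(tx.displacement(pts) - [5.0, 0.0, 0.0], axis=1)
    assert err.mean() < 0.5


def test_register_requires_overlap(small_volume):
    far = volumes.Volume(small_volume.data, small_volume.spacing,
                         small_volume.origin + 1000.0)
    with pytest.raises(ValueError):
        volumes.register(small_volume, far)


def test_watershed_requires_background_marker(small_volume):
    markers = np.zeros(small_volume.shape, dtype=np.int32)
    markers[2, 2, 2] = volumes.BONE
    with pytest.raises(ValueError):
        volumes.segment_watershed(small_volume, markers)


def test_watershed_full_markers_is_identity(small_volume):
    markers = np.full(small_volume.shape, 3, dtype=np.int32)
    markers[:5] = volumes.BONE
    labels = volumes.segment_watershed(small_volume, markers)
    assert np.array_equal(labels.data == volumes.BONE, markers == volumes.BONE)
    assert (labels.data[5:] == volumes.BACKGROUND).all()


def test_watershed_bone_dice_noise_free():
    quiet = phantom.make_case("zone_I_iliac_crest", 1,
                              phantom.PhantomParams(noise_sd=0.0))
    ct = phantom.synth_ct(quiet)
    markers = volumes.auto_markers(ct, volumes.BONE)
    markers = volumes.band_markers(
        ct, volumes.TUMOR, phantom.CT_LEVELS["tumor"] - 160,
        phantom.CT_LEVELS["tumor"] + 160, markers=markers)
    labels = volumes.segment_watershed(ct, markers)
    pts = _grid_points(ct.origin, ct.spacing, ct.shape)
    truth = _labels_at(quiet, pts).reshape(ct.shape)
    assert volumes.dice(labels.data == 1, truth == 1) >= 0.99


def test_apply_transform_identity(registration_setup):
    gt = registration_setup["gt"]
    mesh = registration_setup["case"].tumor
    zero = phantom.GroundTruthTransform(
        gt.control_origin, gt.control_spacing,
        np.zeros_like(gt.control_field))
    out = volumes.apply_transform(mesh, zero)
    np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-9)


def test_ground_truth_maps_mr_tumor_mask_into_ct_frame(registration_setup):
    case = registration_setup["case"]
    mr, gt = registration_setup["mr"], registration_setup["gt"]
    ct = registration_setup["ct"]
    mr_labels = volumes.segment_watershed(
        mr, volumes.auto_markers(mr, volumes.TUMOR))
    gt.fixed_reference = ct
    mapped = volumes.apply_transform(
        volumes.LabelVolume(data=mr_labels.data, spacing=mr.spacing,
                            origin=mr.origin), gt)
    pts = _grid_points(ct.origin, ct.spacing, ct.shape)
    truth = _labels_at(case, pts).reshape(ct.shape)
    assert volumes.dice(mapped.data == 2, truth == 2) >= 0.95


def test_mesh_and_mask_transform_paths_agree(registration_setup):
    """Mapping the tumor as a mesh or as a voxel mask must land in the same
    place (within a voxel)."""
    case = registration_setup["case"]
    gt = registration_setup["gt"]
    # a tumor mesh expressed in the moving (MR) frame
    mr_tumor = case.tumor.copy()
    mr_tumor.vertices = gt.map_fixed_to_moving(np.asarray(mr_tumor.vertices))
    back = volumes.apply_transform(mr_tumor, gt)
    err = np.linalg.norm(back.vertices - case.tumor.vertices, axis=1)
    assert err.max() < 1.0


def test_extract_surface_sphere_volume():
    r, spacing = 20.0, 1.0
    ax = np.arange(-26, 27) * spacing
    xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (xs**2 + ys**2 + zs**2) < r**2
    labels = volumes.LabelVolume(data=mask.astype(np.int32),
                                 spacing=(spacing,) * 3,
                                 origin=(-26.0, -26.0, -26.0))
    mesh = volumes.extract_surface(labels, 1)
    assert mesh.is_watertight
    want = 4.0 / 3.0 * np.pi * r**3
    assert abs(mesh.volume - want) / want < 0.02


def test_extract_surface_empty_label():
    labels = volumes.LabelVolume(data=np.zeros((5, 5, 5), dtype=np.int32))
    with pytest.raises(ValueError):
        volumes.extract_surface(labels, 1)


def test_extract_surface_resolution_consistency():
    """Halving the voxel size roughly halves the surface error."""
    r = 15.0
    truth = trimesh.creation.icosphere(subdivisions=4, radius=r)
    maxima = {}
    for spacing in (2.0, 1.0):
        n = int(np.ceil((r + 4) / spacing))
        ax = (np.arange(-n, n + 1) + 0.31) * spacing
        xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = (xs**2 + ys**2 + zs**2) < r**2
        labels = volumes.LabelVolume(
            data=mask.astype(np.int32), spacing=(spacing,) * 3,
            origin=(ax[0],) * 3)
        mesh = volumes.extract_surface(labels, 1)
        maxima[spacing] = meshproc.hausdorff(mesh, truth, symmetric=True)["max"]
        assert maxima[spacing] < 2 * spacing
    ratio = maxima[1.0] / maxima[2.0]
    assert 0.3 < ratio < 0.8


def test_marker_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(4)
    markers = np.zeros((9, 8, 7), dtype=np.int32)
    idx = rng.integers(0, [9, 8, 7], (20, 3))
    markers[idx[:, 0], idx[:, 1], idx[:, 2]] = rng.integers(1, 4, 20)
    p = tmp_path / "seeds.csv"
    volumes.write_markers(markers, p)
    back = volumes.read_markers(p, markers.shape)
    assert np.array_equal(back, markers)


def test_label_conservation_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    lab = volumes.LabelVolume(
        data=rng.integers(0, 3, (15, 16, 17)).astype(np.int32))
    p = tmp_path / "lab.nrrd"
    volumes.write_volume(lab, p)
    back = volumes.read_volume(p)
    ids, counts = np.unique(lab.data, return_counts=True)
    ids2, counts2 = np.unique(back.data.astype(np.int32), return_counts=True)
    assert np.array_equal(ids, ids2) and np.array_equal(counts, counts2)
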