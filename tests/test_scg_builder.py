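import numpy as np
import pytest
import trimesh

from oncocut import meshproc, phantom, scg_builder as scg
from oncocut._voxel import VoxelGrid

from conftest import make_cut_surface
from _oracles import min_dist_brute, read_binary_stl


def test_intersection_circle_closed_form():
    """A plane 12 mm off-center through a 20 mm sphere meets it on a circle
    of radius 16."""
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
    surf = make_cut_surface([12.0, 0, 0], [1, 0, 0], [0, 1, 0])
    chains = scg.intersection_curve(sphere, [surf], approach=[0, 0, 1])
    pts = np.vstack(chains[0]["chains"])
    r = np.sqrt(pts[:, 1] ** 2 + pts[:, 2] ** 2)
    np.testing.assert_allclose(r, 16.0, atol=0.1)
    np.testing.assert_allclose(pts[:, 0], 12.0, atol=1e-8)


def test_intersection_points_on_both_meshes(zone2_case, zone2_plan):
    plan, _ = zone2_plan
    chains = scg.intersection_curve(zone2_case.bone, plan.surfaces,
                                    zone2_case.approach)
    for cd, surf in zip(chains, plan.surfaces):
        for ch in cd["chains"]:
            d_bone = meshproc.surface_distance(ch, zone2_case.bone)
            d_plane = np.abs((ch - surf.plane_point) @ surf.plane_normal)
            assert d_bone.max() < 0.05
            assert d_plane.max() < 0.05


def test_intersection_splits_at_foramen():
    """A cut through a sacral foramen interrupts the guide-facing curve."""
    case = phantom.make_case("zone_I_IV_sacroiliac", 1)
    # plane through the upper foramen (z = 105, axis along y), approach +y
    surf = make_cut_surface([30.0, 70.0, 105.0], [0, 0, 1], [1, 0, 0])
    chains = scg.intersection_curve(case.bone, [surf], approach=[0, 1, 0])
    assert len(chains[0]["chains"]) >= 2


def test_intersection_requires_hit():
    sphere = trimesh.creation.icosphere(2, radius=5.0)
    surf = make_cut_surface([50.0, 0, 0], [1, 0, 0], [0, 1, 0], half_extent=3)
    with pytest.raises(ValueError):
        scg.intersection_curve(sphere, [surf], approach=[0, 0, 1])


def test_trajectory_single_chain_two_nodes():
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=20.0)
    surf = make_cut_surface([12.0, 0, 0], [1, 0, 0], [0, 1, 0])
    chains = scg.intersection_curve(sphere, [surf], approach=[0, 0, 1])
    traj = scg.make_trajectory(chains, [surf])
    non_bridge = [s for s in traj.spans if not s["is_bridge"]]
    assert len(non_bridge) == 1
    assert len(traj.nodes) == 2


def test_trajectory_sacroiliac_node_count(zone2_case):
    """Four cutting planes give 2 extremities + 3 junction nodes."""
    from oncocut import pipeline

    case = phantom.make_case("zone_I_IV_sacroiliac", 1)
    plan, _ = pipeline.plan_case(case)
    assert plan.n_segments == 4
    chains = scg.intersection_curve(case.bone, plan.surfaces, case.approach)
    traj = scg.make_trajectory(chains, plan.surfaces, tumor=case.tumor)
    assert len(traj.nodes) == 5


def test_trajectory_smoothing_stays_near_chain(zone2_case, zone2_build):
    from oncocut.scg_builder import _polyline_deviation

    for cd in zone2_build["chains"]:
        for ch in cd["chains"]:
            sm = scg._smooth_chain(ch)
            assert _polyline_deviation(sm, ch) < 0.5


def test_trajectory_rejects_tiny_total():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=2.5)
    surf = make_cut_surface([1.0, 0, 0], [1, 0, 0], [0, 1, 0])
    chains = scg.intersection_curve(sphere, [surf], approach=[0, 0, 1])
    with pytest.raises(ValueError):
        scg.make_trajectory(chains, [surf], anchor_radius=10.0)


def _straight_trajectory(length=50.0):
    pts = np.column_stack([np.linspace(0, length, 26),
                           np.zeros(26), np.zeros(26)])
    return scg.GuideTrajectory(
        nodes=np.array([pts[0], pts[-1]]),
        spans=[{"points": pts, "surface_index": 0, "is_bridge": False}])


def test_main_body_cylinder_volume_and_diameter():
    traj = _straight_trajectory(50.0)
    body = scg.main_body(traj, 16.0)
    assert body.is_watertight
    want = np.pi * 8.0**2 * 50.0
    assert abs(body.volume - want) / want < 0.01
    # cross-section diameter perpendicular to the trajectory
    from oncocut import metrology
    assert abs(metrology.sweep_diameter(body, traj) - 16.0) < 0.1


def test_main_body_quarter_circle_torus_sector():
    theta = np.linspace(0, np.pi / 2, 64)
    R = 40.0
    pts = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                           np.zeros_like(theta)])
    traj = scg.GuideTrajectory(
        nodes=np.array([pts[0], pts[-1]]),
        spans=[{"points": pts, "surface_index": 0, "is_bridge": False}])
    body = scg.main_body(traj, 16.0, step=0.5)
    want = np.pi * 8.0**2 * (np.pi * R / 2.0)  # Pappus
    assert abs(body.volume - want) / want < 0.02


def test_anchors_per_node_diameter_volume():
    traj = _straight_trajectory()
    spheres = scg.anchors(traj, 20.0)
    assert len(spheres) == len(traj.nodes)
    from oncocut import metrology
    for s in spheres:
        assert abs(metrology.anchor_diameter(s) - 20.0) < 0.1
        want = 4.0 / 3.0 * np.pi * 10.0**3
        assert abs(s.volume - want) / want < 0.01


def test_guiding_feature_dimensions_and_flushness(zone2_plan, zone2_build):
    from oncocut import metrology

    plan, _ = zone2_plan
    for g in zone2_build["guiding"]:
        assert g.is_watertight
        assert abs(metrology.guiding_height(g) - 15.0) < 0.1
        assert abs(metrology.guiding_thickness(g) - 7.0) < 0.1
        # the inner face lies exactly on its resection surface
        surf = plan.surfaces[g.metadata["surface_index"]]
        k = g.metadata["n_points"]
        inner = np.asarray(g.vertices[:2 * k])
        dev = np.abs((inner - surf.plane_point) @ surf.plane_normal)
        assert dev.max() < 0.05


def test_csw_thickness_conformity_and_width(zone2_case, zone2_build):
    from oncocut import metrology

    csw = zone2_build["csw"]
    surf = zone2_build["csw_surface"]
    assert csw.is_watertight
    assert abs(metrology.patch_thickness(csw) - 5.0) < 0.1
    # inner face vertices sit on the bone
    nv = len(csw.vertices) // 2
    d = meshproc.surface_distance(np.asarray(csw.vertices[:nv]),
                                  zone2_case.bone)
    assert d.max() < 0.1
    # trimmed width: the patch stays within csw_max_width of the cut plane
    g = (np.asarray(csw.vertices) - surf.plane_point) @ surf.plane_normal
    assert g.max() <= zone2_build["params"].csw_max_width + 5.0 + 0.1


def test_csw_flat_patch_is_slab():
    plate = trimesh.creation.box(extents=(60, 60, 4))
    solid = scg.contact_surface_widening(plate, np.array([0.0, 0.0, 2.0]),
                                         csw_thickness=5.0, patch_radius=15.0)
    assert solid.is_watertight
    zs = solid.vertices[:, 2]
    assert abs((zs.max() - zs.min()) - 5.0) < 0.1


def test_csw_rejects_margin_zone(zone2_case, zone2_plan):
    plan, _ = zone2_plan
    point_on_tumor = np.asarray(zone2_case.tumor.vertices[0])
    with pytest.raises(ValueError):
        scg.contact_surface_widening(zone2_case.bone, point_on_tumor,
                                     tumor=zone2_case.tumor, margin=10.0)


def test_clip_on_thin_plate(zone1_case):
    solids, info = scg.deformable_clip(zone1_case.bone, zone1_case.clip_point,
                                       zone1_case.approach)
    assert len(solids) == 3
    for s in solids:
        assert s.is_watertight
    assert info["edge_thickness"] < 12.0
    np.testing.assert_allclose(
        info["sphere_gap"], info["edge_thickness"] + 2 * 0.25, atol=1e-6)
    assert abs(info["bridge_thickness"] - 5.0) < 0.1
    # measured gap between the two sphere meshes matches the fit target
    d = meshproc.surface_distance(np.asarray(solids[0].vertices), solids[1])
    assert abs(d.min() - info["sphere_gap"]) < 0.1


def test_clip_rejects_thick_region():
    thick = trimesh.creation.box(extents=(40.0, 16.0, 30.0))
    v, f = thick.vertices, thick.faces
    for _ in range(3):
        v, f = trimesh.remesh.subdivide(v, f)
    thick = trimesh.Trimesh(v, f, process=False)
    with pytest.raises(ValueError):
        scg.deformable_clip(thick, np.array([0.0, 0.0, 15.0]),
                            np.array([0.0, 0.0, 1.0]))


def test_fixation_dimensions_and_axes(zone2_case, zone2_build):
    from oncocut import metrology

    axes = zone2_build["axes"]
    bosses = zone2_build["fixation"][0::2]
    assert len(axes) >= 2
    b0, (p0, a0) = bosses[0], axes[0]
    assert abs(metrology.bore_diameter(b0, p0, a0) - 2.1) < 0.05
    v = np.asarray(b0.vertices) - p0
    radial = v - np.outer(v @ a0, a0)
    assert abs(2 * np.linalg.norm(radial, axis=1).max() - 6.0) < 0.1
    # the bore clears a 2 mm K-wire
    assert zone2_build["params"].fixation_inner > zone2_build["params"].kwire_diameter
    # no two axes parallel (exhaustive pairwise)
    assert scg.min_pairwise_angle(axes) > 0.0
    assert scg.min_pairwise_angle(axes) >= zone2_build["params"].min_pairwise_axis_angle - 1e-9
    # axes clear the tumor + margin zone
    for p, a in axes:
        pts = p[None, :] + np.linspace(-40, 30, 30)[:, None] * a[None, :]
        d = min_dist_brute(pts[::3], np.asarray(zone2_case.tumor.triangles))
        assert d.min() >= 10.0


def test_union_of_two_spheres_single_component():
    a = trimesh.creation.icosphere(3, radius=8.0)
    b = trimesh.creation.icosphere(3, radius=8.0)
    b.apply_translation([6.0, 0, 0])
    grid = VoxelGrid.empty([-10, -10, -10], [16, 10, 10], 0.25)
    grid.add_mesh(a)
    grid.add_mesh(b)
    mesh = grid.to_mesh()
    assert mesh.is_watertight
    assert mesh.body_count == 1


def test_finish_watertight_with_corner_gaps(zone2_model, zone2_plan):
    plan, _ = zone2_plan
    model = zone2_model
    assert model.solid.is_watertight
    n_junctions = sum(1 for s in plan.surfaces if s.junction_end is not None)
    assert model.metadata["n_corner_gaps"] == n_junctions
    assert len(model.contact_region.faces) > 0
    assert model.metadata["qc"]["watertight"]


def test_finish_volume_matches_voxel_oracle(zone2_model):
    """Union volume agrees with a voxel recount at a different pitch."""
    model = zone2_model
    grid = VoxelGrid.empty(model.solid.bounds[0], model.solid.bounds[1], 0.4)
    grid.add_mesh(model.solid)
    assert abs(grid.volume() - model.solid.volume) / model.solid.volume < 0.02


def test_guide_clears_tumor(zone2_case, zone2_model):
    d = meshproc.surface_distance(
        np.asarray(zone2_case.tumor.vertices), zone2_model.solid)
    assert d.min() > 0.0


def test_export_roundtrip_and_second_parser(tmp_path, zone2_model):
    p = tmp_path / "guide.stl"
    scg.export_guide(zone2_model, p)
    back = meshproc.load_mesh(p)
    assert abs(back.volume - zone2_model.solid.volume) \
        < 1e-6 * abs(zone2_model.solid.volume)
    tris = read_binary_stl(p)
    assert len(tris) == len(zone2_model.solid.faces)


def test_export_refuses_open_mesh(tmp_path):
    open_mesh = trimesh.creation.icosahedron()
    open_mesh = trimesh.Trimesh(open_mesh.vertices, open_mesh.faces[:-1],
                                process=False)
    model = scg.SCGModel(solid=open_mesh, bodies={}, pin_axes=[],
                         contact_region=open_mesh, params=scg.GuideParams())
    with pytest.raises(ValueError):
        scg.export_guide(model, tmp_path / "bad.stl")


def test_guide_params_validation():
    with pytest.raises(ValueError):
        scg.GuideParams(fixation_inner=1.9)  # below the K-wire diameter
    with pytest.raises(ValueError):
        scg.GuideParams(guiding_height=-1.0)
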