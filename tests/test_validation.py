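import numpy as np
import pytest
import trimesh

from oncocut import phantom, planning, validation

from conftest import make_cut_surface
from _oracles import min_dist_brute


def test_achieved_margin_sphere_plane_closed_form():
    """Sphere r=15 against a plane 27 mm from its center: margin 12."""
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=15.0)
    surf = make_cut_surface([27.0, 0, 0], [1, 0, 0], [0, 1, 0])
    margins = validation.achieved_margin(sphere, [surf])
    assert abs(margins[0] - 12.0) < 0.05


def test_achieved_margin_matches_brute_oracle(zone2_case, zone2_plan):
    plan, _ = zone2_plan
    margins = validation.achieved_margin(zone2_case.tumor, plan.surfaces)
    for i, surf in enumerate(plan.surfaces):
        want = min_dist_brute(np.asarray(zone2_case.tumor.vertices)[::9],
                              np.asarray(surf.mesh.triangles)).min()
        # sampling can only find smaller-or-equal minima than the
        # vertex-subset oracle
        assert margins[i] <= want + 1e-9
        assert margins[i] >= want - 0.5


@pytest.fixture(scope="module")
def cut_zone2():
    case = phantom.make_case("zone_II_acetabulum", 1)
    from oncocut import pipeline

    plan, _ = pipeline.plan_case(case)
    piece, rest, rep = validation.simulate_cut(
        case.bone, plan.surfaces, blade_thickness=2.0, tumor=case.tumor,
        approach=case.approach)
    return case, plan, piece, rest, rep


def test_simulate_cut_no_breach_and_through(cut_zone2):
    _, _, piece, rest, rep = cut_zone2
    assert rep["breach"] is False
    assert rep["through_cut"]
    assert piece.is_watertight and rest.is_watertight
    assert rep["extractable"] is True


def test_simulate_cut_kerf_volume_oracle(cut_zone2):
    """Removed volume ~ sum of in-bone cut-section areas x kerf width,
    with the section areas sampled from the analytic bone field."""
    case, plan, _, _, rep = cut_zone2
    area = 0.0
    step = 0.4
    for surf in plan.surfaces:
        n = surf.plane_normal
        u = surf.mesh.vertices[1] - surf.mesh.vertices[0]
        u = u / np.linalg.norm(u)
        v = np.cross(n, u)
        uu, vv = np.meshgrid(np.arange(-120, 120, step),
                             np.arange(-120, 120, step), indexing="ij")
        pts = (surf.plane_point + uu[..., None] * u
               + vv[..., None] * v).reshape(-1, 3)
        inside = case.bone_sdf(pts) < 0
        for other in plan.surfaces:
            if abs(other.segment_index - surf.segment_index) == 1:
                inside &= (pts - other.plane_point) @ other.plane_normal <= 1.0
        area += inside.sum() * step * step
    assert abs(rep["removed_volume"] - 2.0 * area) / (2.0 * area) < 0.1


def test_reversed_draft_blocks_extraction():
    """A piece that tapers with depth extracts along the approach; the
    reversed tilt wedges it under the remaining bone."""
    from conftest import make_cut_surface

    bone = trimesh.creation.box(extents=(60, 60, 30))
    tumor = trimesh.creation.icosphere(2, radius=5.0)
    th = np.deg2rad(8.0)

    def surfaces(sign):
        # plane ~x=12; with depth (-z) it moves by sign * tan(th) toward -x
        n = np.array([np.cos(th), 0.0, sign * np.sin(th)])
        return [make_cut_surface([12.0, 0.0, 0.0], n, [0, 1, 0],
                                 half_extent=80.0)]

    # s=-1: the piece (x < plane, holding the tumor) narrows with depth
    ok = validation.simulate_cut(bone, surfaces(-1.0), 2.0, tumor=tumor,
                                 approach=[0, 0, 1], pitch=0.5)[2]
    bad = validation.simulate_cut(bone, surfaces(+1.0), 2.0, tumor=tumor,
                                  approach=[0, 0, 1], pitch=0.5)[2]
    assert ok["extractable"] is True
    assert bad["extractable"] is False


def test_conformity_own_bone_within_band(zone2_case, zone2_model):
    stats = validation.conformity(zone2_model, zone2_case.bone)
    assert stats["min"] >= -0.05
    assert stats["max"] <= 0.5


def test_conformity_discriminates_misplaced_guide(zone2_case, zone2_model):
    """A 2 mm seating error shows up immediately in the conformity stats."""
    shifted = zone2_case.bone.copy()
    shifted.apply_translation([2.0, 0.0, 0.0])
    good = validation.conformity(zone2_model, zone2_case.bone)
    bad = validation.conformity(zone2_model, shifted)
    assert bad["min"] < -0.5 or bad["max"] > 4 * abs(good["max"])


def test_conformity_signed_distance_matches_oracle(zone2_case, zone2_model):
    """The fast signed-distance path agrees with the brute-force oracle on
    the same contact-region sample points."""
    from _oracles import point_in_mesh_ray

    from oncocut._dist import points_in_mesh
    from oncocut.meshproc import surface_distance

    from oncocut.meshproc import decimate

    region = zone2_model.contact_region
    samples, _ = trimesh.sample.sample_surface(region, 60, seed=11)
    samples = np.ascontiguousarray(samples, dtype=np.float64)
    # a small decimated bone keeps the brute-force oracle affordable; the
    # kernels under test are mesh-size independent
    bone = decimate(zone2_case.bone, 2000)
    fast = surface_distance(samples, bone)
    fast_in = points_in_mesh(samples, np.ascontiguousarray(bone.triangles))
    slow = min_dist_brute(samples, np.asarray(bone.triangles))
    slow_in = point_in_mesh_ray(samples, bone)
    np.testing.assert_allclose(fast, slow, atol=1e-9)
    assert (fast_in == slow_in).mean() > 0.95  # containment ties at d ~ 0


def test_printability_pass_and_thin_slab_flag(zone2_model):
    rep = validation.printability(zone2_model)
    assert rep["hole_ok"]  # the 2.1 mm bore clears the 1 mm hole minimum
    assert rep["wall_ok"]
    # a 0.5 mm slab is flagged by the same transform
    slab = trimesh.creation.box(extents=(20.0, 20.0, 0.5))
    thin_model = validation.SCGModel(
        solid=slab, bodies={}, pin_axes=[], contact_region=slab,
        params=zone2_model.params)
    thin = validation.printability(thin_model, pitch=0.1)
    assert not thin["wall_ok"]


def test_thickness_transform_cylinder_oracle():
    from oncocut.scg_builder import GuideParams

    cyl = trimesh.creation.cylinder(radius=5.0, height=40.0, sections=64)
    model = validation.SCGModel(solid=cyl, bodies={}, pin_axes=[],
                                contact_region=cyl, params=GuideParams())
    rep = validation.printability(model, pitch=0.2)
    assert abs(rep["max_inscribed_diameter"] - 10.0) / 10.0 < 0.05


def test_design_report_serializes_and_passes(zone2_case, zone2_plan, zone2_model):
    import json

    plan, _ = zone2_plan
    report = validation.build_report(zone2_model, zone2_case.bone,
                                     zone2_case.tumor, plan)
    assert report.passed
    payload = json.loads(json.dumps(report.to_dict(), default=float))
    assert payload["tumor_breach"] is False
    md = report.to_markdown()
    assert "PASS" in md


def test_stability_patches_multi_plane(zone2_model):
    patches = validation.stability_patches(zone2_model)
    assert patches["n_patches"] >= 1
    assert patches["spread"] >= 0.0
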