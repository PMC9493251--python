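import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString

from oncocut import planning

from _oracles import min_dist_brute, rasterize_polygon_area


def test_plane_from_points_axis_aligned():
    pl = planning.plane_from_points([0, 0, 0], [1, 0, 0], [0, 1, 0])
    np.testing.assert_allclose(pl.normal, [0, 0, 1], atol=1e-12)


def test_plane_cyclic_permutation_same_normal():
    pts = [np.array([1.0, 2, 3]), np.array([4.0, 1, 0]), np.array([2.0, 5, 1])]
    n0 = planning.plane_from_points(*pts).normal
    n1 = planning.plane_from_points(pts[1], pts[2], pts[0]).normal
    np.testing.assert_allclose(n0, n1, atol=1e-12)


def test_plane_collinear_rejected():
    with pytest.raises(ValueError):
        planning.plane_from_points([0, 0, 0], [1, 1, 1], [2, 2, 2])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_plane_contains_its_points(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-50, 50, (3, 3))
    area = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
    if area < 1e-3:
        return
    pl = planning.plane_from_points(*pts)
    for p in pts:
        assert abs(np.dot(p - pl.origin, pl.normal)) < 1e-9
    # basis is orthonormal
    np.testing.assert_allclose(
        [pl.basis_u @ pl.basis_u, pl.basis_v @ pl.basis_v,
         pl.basis_u @ pl.basis_v], [1, 1, 0], atol=1e-9)


@pytest.fixture(scope="module")
def plane_z():
    return planning.plane_from_points([0, 0, 40], [1, 0, 40], [0, 1, 40])


def test_silhouette_of_sphere_is_circle(plane_z):
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=15.0)
    sil = planning.silhouette(sphere, plane_z)
    r = np.linalg.norm(np.asarray(sil.exterior.coords), axis=1)
    assert r.max() <= 15.0 + 1e-6
    assert r.min() > 15.0 - 0.1  # chord-discretization error


def test_silhouette_area_vs_rasterization_oracle(plane_z):
    blob = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    blob.vertices *= np.array([1.0, 0.6, 0.8])
    sil = planning.silhouette(blob, plane_z)
    uv = plane_z.to_2d(blob.vertices)
    want = rasterize_polygon_area(uv[blob.faces], pixel=0.1)
    assert abs(sil.area - want) / want < 0.005
    # union area is at least any single projected triangle
    tri_areas = [0.5 * abs(np.cross(t[1] - t[0], t[2] - t[0]))
                 for t in uv[blob.faces]]
    assert sil.area >= max(tri_areas)


def test_silhouette_empty_rejected(plane_z):
    empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3)))
    with pytest.raises(ValueError):
        planning.silhouette(empty, plane_z)


def test_offset_zero_is_identity(plane_z):
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
    sil = planning.silhouette(sphere, plane_z)
    assert planning.offset_margin(sil, 0.0).equals(sil)


def test_offset_circle_by_margin(plane_z):
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=15.0)
    sil = planning.silhouette(sphere, plane_z)
    off = planning.offset_margin(sil, 12.0)
    r = np.linalg.norm(np.asarray(off.exterior.coords), axis=1)
    assert abs(r.max() - 27.0) < 0.05
    assert abs(r.min() - 27.0) < 0.15


def test_offset_min_distance_oracle(plane_z):
    blob = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    blob.vertices *= np.array([1.0, 0.55, 0.9])
    sil = planning.silhouette(blob, plane_z)
    off = planning.offset_margin(sil, 12.0)
    ring = LineString(sil.exterior.coords)
    out = LineString(off.exterior.coords)
    samples = [out.interpolate(t) for t in
               np.linspace(0, out.length, 1500, endpoint=False)]
    d = np.array([p.distance(ring) for p in samples])
    assert abs(d.min() - 12.0) < 0.05


def test_offset_rejects_self_intersecting():
    bowtie = planning.Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
    with pytest.raises(ValueError):
        planning.offset_margin(bowtie, 1.0)


def _offset_circle(plane):
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
    sil = planning.silhouette(sphere, plane)
    return sil, planning.offset_margin(sil, 12.0)


@pytest.mark.parametrize("n_segments", [1, 2, 3, 4])
def test_fit_polyline_respects_offset(plane_z, n_segments):
    sil, off = _offset_circle(plane_z)
    bone_uv = np.array([[-80, -80], [80, -80], [80, 80], [-80, 80]], float)
    poly = planning.fit_polyline(off, n_segments, [1.0, 0.0], bone_uv)
    assert len(poly) == n_segments + 1
    assert LineString(poly).is_simple
    # every polyline point keeps the planned offset from the silhouette
    ring = LineString(sil.exterior.coords)
    line = LineString(poly)
    samples = [line.interpolate(t) for t in
               np.linspace(0, line.length, 800)]
    d = np.array([p.distance(ring) for p in samples])
    assert d.min() >= 12.0 - 0.05
    # endpoints beyond the bone's projected extent
    reach = np.linalg.norm(bone_uv, axis=1).max()
    assert np.linalg.norm(poly[0]) > reach
    assert np.linalg.norm(poly[-1]) > reach


def test_fit_polyline_rejects_bad_segment_count(plane_z):
    _, off = _offset_circle(plane_z)
    bone_uv = np.zeros((4, 2))
    with pytest.raises(ValueError):
        planning.fit_polyline(off, 5, [1, 0], bone_uv)


def _single_plane_plan(draft=5.0):
    plane = planning.plane_from_points([0, 0, 40], [1, 0, 40], [0, 1, 40])
    poly = np.array([[27.0, -80.0], [27.0, 80.0]])
    return planning.ResectionPlan(plane=plane, polyline=poly,
                                  draft_angle=draft,
                                  start_height=0.0, extrusion_depth=60.0)


@pytest.mark.parametrize("draft,expect", [(0.0, 90.0), (5.0, 85.0)])
def test_extrusion_draft_angle(draft, expect):
    plan = _single_plane_plan(draft)
    surfs = planning.extrude_resection_surfaces(
        plan, tumor_uv_centroid=np.zeros(2))
    n = plan.plane.normal
    for s in surfs:
        ang = np.degrees(np.arccos(abs(np.dot(s.plane_normal, n))))
        assert abs(ang - expect) < 0.01


def test_adjacent_surfaces_share_junction():
    plane = planning.plane_from_points([0, 0, 40], [1, 0, 40], [0, 1, 40])
    poly = np.array([[40.0, -60.0], [30.0, 0.0], [40.0, 60.0]])
    plan = planning.ResectionPlan(plane=plane, polyline=poly,
                                  start_height=0.0, extrusion_depth=50.0)
    s0, s1 = planning.extrude_resection_surfaces(
        plan, tumor_uv_centroid=np.zeros(2))
    assert s0.junction_end is not None and s1.junction_start is not None
    p, d = s0.junction_end
    for s in (s0, s1):
        assert abs(np.dot(p - s.plane_point, s.plane_normal)) < 1e-6
        assert abs(np.dot(d, s.plane_normal)) < 1e-9
    # the shared top vertex lies on both planes (construction)
    shared = s0.mesh.vertices[1]
    assert np.linalg.norm(shared - s1.mesh.vertices[0]) < 1e-9


def test_validate_plan_sphere_margin_and_oracle():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
    sphere.apply_translation([0, 0, -10.0])
    plan = _single_plane_plan(5.0)
    report = planning.validate_plan(plan, sphere,
                                    tumor_uv_centroid=np.zeros(2))
    assert report["satisfied"]
    assert report["achieved_margin"][0] >= 10.0
    # the reported minimum matches the brute-force oracle
    want = min_dist_brute(np.asarray(sphere.vertices),
                          np.asarray(plan.surfaces[0].mesh.triangles)).min()
    assert abs(report["achieved_margin"][0] - want) < 0.05


def test_validate_plan_per_segment_override():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
    sphere.apply_translation([0, 0, -10.0])
    plane = planning.plane_from_points([0, 0, 40], [1, 0, 40], [0, 1, 40])
    poly = np.array([[21.0, -80.0], [21.0, 80.0]])
    plan = planning.ResectionPlan(plane=plane, polyline=poly,
                                  segment_margins={0: 5.0},
                                  start_height=0.0, extrusion_depth=60.0)
    report = planning.validate_plan(plan, sphere,
                                    tumor_uv_centroid=np.zeros(2))
    assert report["required_margin"][0] == 5.0
    assert report["satisfied"]
    assert report["achieved_margin"][0] >= 5.0
    # the local reduction asks for less outward motion than the baseline
    baseline = planning.ResectionPlan(
        plane=plan.plane, polyline=np.array([[21.0, -80.0], [21.0, 80.0]]),
        start_height=0.0, extrusion_depth=60.0)
    base_report = planning.validate_plan(baseline, sphere,
                                         tumor_uv_centroid=np.zeros(2))
    assert report["expanded_by"][0] < base_report["expanded_by"][0]


def test_validate_plan_pushes_violating_segment_outward():
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
    sphere.apply_translation([0, 0, -10.0])
    plane = planning.plane_from_points([0, 0, 40], [1, 0, 40], [0, 1, 40])
    poly = np.array([[20.0, -80.0], [20.0, 80.0]])  # only 5 mm clearance
    plan = planning.ResectionPlan(plane=plane, polyline=poly,
                                  start_height=0.0, extrusion_depth=60.0)
    report = planning.validate_plan(plan, sphere,
                                    tumor_uv_centroid=np.zeros(2))
    assert report["satisfied"]
    assert report["expanded_by"][0] > 2.0
    assert report["achieved_margin"][0] >= 10.0


def test_draft_tapers_piece_with_depth():
    """With a positive draft the cut surface creeps toward the piece."""
    plan = _single_plane_plan(5.0)
    (surf,) = planning.extrude_resection_surfaces(
        plan, tumor_uv_centroid=np.zeros(2))
    v = surf.mesh.vertices
    top = v[:2].mean(axis=0)
    bottom = v[-2:].mean(axis=0)
    # at depth the surface has moved toward the tumor side (-x here)
    assert bottom[0] < top[0] - 1.0
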