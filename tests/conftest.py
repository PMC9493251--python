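import numpy as np
import pytest
import trimesh

from oncocut import phantom, pipeline, scg_builder as scg
from oncocut._dist import closest_point_on_triangles


@pytest.fixture(scope="session")
def zone2_case():
    return phantom.make_case("zone_II_acetabulum", 1)


@pytest.fixture(scope="session")
def zone1_case():
    return phantom.make_case("zone_I_iliac_crest", 1)


@pytest.fixture(scope="session")
def zone2_plan(zone2_case):
    plan, report = pipeline.plan_case(zone2_case)
    return plan, report


@pytest.fixture(scope="session")
def zone2_build(zone2_case, zone2_plan):
    """All guide bodies for the acetabular preset with default parameters."""
    case = zone2_case
    plan, _ = zone2_plan
    params = scg.GuideParams()
    chains = scg.intersection_curve(case.bone, plan.surfaces, case.approach)
    traj = scg.make_trajectory(chains, plan.surfaces, tumor=case.tumor)
    main = scg.main_body(traj, params.sweep_diameter)
    anchor_bodies = scg.anchors(traj, params.anchor_diameter)
    guiding = scg.guiding_feature(plan.surfaces, traj, case.approach,
                                  params.guiding_height,
                                  params.guiding_thickness)
    fixation, axes = scg.fixation_features(
        plan.surfaces, traj, case.approach, params, tumor=case.tumor)
    span = max((s for s in traj.spans if not s["is_bridge"]),
               key=lambda s: len(s["points"]))
    surf = plan.surfaces[span["surface_index"]]
    mid = span["points"][len(span["points"]) // 2]
    _, cp, _ = closest_point_on_triangles(
        (mid + 18.0 * surf.plane_normal)[None, :],
        np.ascontiguousarray(case.bone.triangles))
    csw = scg.contact_surface_widening(
        case.bone, cp[0], limit_surface=surf, tumor=case.tumor)
    return {
        "params": params, "chains": chains, "traj": traj, "main": main,
        "anchors": anchor_bodies, "guiding": guiding, "fixation": fixation,
        "axes": axes, "csw": csw, "csw_surface": surf,
    }


@pytest.fixture(scope="session")
def zone2_model(zone2_case, zone2_plan, zone2_build):
    b = zone2_build
    bodies = {
        "main_body": [b["main"]], "anchors": b["anchors"],
        "guiding": b["guiding"], "csw": [b["csw"]], "fixation": b["fixation"],
    }
    plan, _ = zone2_plan
    return scg.finish(bodies, zone2_case.bone, plan.surfaces, b["traj"],
                      zone2_case.approach, b["params"], pin_axes=b["axes"],
                      csw_limits=[(b["csw_surface"], b["params"].csw_max_width)])


@pytest.fixture(scope="session")
def registration_setup(zone1_case):
    """Pseudo-CT, deformed pseudo-MR, ground truth field and the recovered
    transform for the iliac-crest case (shared: registration is the most
    expensive stage)."""
    from oncocut import volumes

    ct = phantom.synth_ct(zone1_case)
    mr, gt = phantom.synth_mr(zone1_case)
    tx = volumes.register(ct, mr)
    return {"case": zone1_case, "ct": ct, "mr": mr, "gt": gt, "tx": tx}


@pytest.fixture(scope="session")
def dense_decimated():
    """Oversampled phantom bone (>2M faces) and its decimated copy."""
    from oncocut import meshproc

    case = phantom.make_case("zone_II_acetabulum", 1,
                             phantom.PhantomParams(mesh_pitch=0.8))
    dense = phantom.dense_bone(case)
    dec = meshproc.decimate(dense, 100_000)
    return {"dense": dense, "decimated": dec}


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The full digital chain run twice with the same seed (determinism
    checks share this; the guide union runs at a 0.4 mm pitch to keep the
    doubled run affordable -- the determinism property is pitch-independent)."""
    outs = []
    reports = []
    for i in range(2):
        out = tmp_path_factory.mktemp(f"run{i}")
        cfg = pipeline.RunConfig(case="zone_II_acetabulum", seed=1,
                                 out_dir=str(out),
                                 guide={"voxel_pitch": 0.4})
        reports.append(pipeline.run(cfg))
        outs.append(out)
    return reports, outs


@pytest.fixture()
def unit_sphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


def make_cut_surface(plane_point, plane_normal, t_dir, half_extent=60.0,
                     segment_index=0):
    """Minimal planar ResectionSurface for direct geometric tests."""
    from oncocut.planning import ResectionSurface

    p = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    t = np.asarray(t_dir, dtype=float)
    t = t - np.dot(t, n) * n
    t = t / np.linalg.norm(t)
    s = np.cross(n, t)
    verts = np.array([
        p - half_extent * t - half_extent * s,
        p + half_extent * t - half_extent * s,
        p - half_extent * t + half_extent * s,
        p + half_extent * t + half_extent * s,
    ])
    mesh = trimesh.Trimesh(vertices=verts, faces=[[0, 1, 3], [0, 3, 2]],
                           process=False)
    return ResectionSurface(mesh=mesh, plane_point=p, plane_normal=n,
                            segment_index=segment_index,
                            seg_a2d=np.zeros(2), seg_b2d=np.array([1.0, 0.0]))
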