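"""Adapter solid modeling: clouds, alpha shape, STL, feasibility."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from psaforge.errors import (
    AlphaTooSmallError,
    CollisionError,
    MeshNotWatertightError,
    ValidationError,
    WorkspaceInfeasibleError,
)
from psaforge.frames import FRAME_BASE, FRAME_RSC, RigidTransform
from psaforge.geometry import (
    PSABuildSpec,
    alpha_shape,
    check_feasibility,
    export_stl,
    fit_interface_frame,
    generate_submodel_clouds,
    sample_feasible_poses,
    solidify,
)

PITCH = 0.5


def cube_cloud(side=10.0, pitch=0.4):
    ax = np.linspace(0.0, side, int(round(side / pitch)) + 1)
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)


def upright_pose(height=22.0, x=0.0, y=0.0):
    return RigidTransform.translation_only([x, y, height], FRAME_RSC, FRAME_BASE)


def tilted_pose(tilt_deg, height=22.0):
    t = RigidTransform.from_rotvec([tilt_deg, 0, 0], [0, 0, height])
    return t.relabel(from_frame=FRAME_RSC, to_frame=FRAME_BASE)


class TestAlphaShape:
    def test_cube_volume_and_watertightness(self):
        mesh = alpha_shape(cube_cloud(10.0, 0.4), alpha=0.8)
        assert mesh.is_watertight
        assert mesh.body_count == 1
        assert mesh.volume == pytest.approx(1000.0, rel=0.05)

    def test_hemisphere_volume_matches_analytic(self):
        # finer pitch than the cube case: a curved boundary interpolates
        # lattice points lying inside the true surface, shrinking the volume
        # by O(pitch/r)
        pts = cube_cloud(10.0, 0.25) - [5.0, 5.0, 0.0]
        pts = pts[(np.linalg.norm(pts, axis=1) <= 5.0) & (pts[:, 2] >= 0)]
        mesh = alpha_shape(pts, alpha=0.5)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(2.0 / 3.0 * np.pi * 125.0, rel=0.05)

    def test_separated_clouds_raise_alpha_too_small(self):
        a = cube_cloud(4.0, 0.5)
        b = a + [10.0, 0, 0]  # 6 mm gap >> alpha
        with pytest.raises(AlphaTooSmallError) as err:
            alpha_shape(np.vstack([a, b]), alpha=1.0)
        assert err.value.suggested_alpha is not None

    def test_volume_monotone_in_alpha(self):
        pts = cube_cloud(6.0, 0.5)
        volumes = [alpha_shape(pts, a).volume for a in (0.5 * np.sqrt(3), 1.0, 1.5, 2.0)]
        assert all(b >= a - 1e-6 for a, b in zip(volumes, volumes[1:]))


class TestSubmodelClouds:
    def test_upright_pose_geometry(self):
        spec = PSABuildSpec(cloud_pitch=PITCH)
        geo = generate_submodel_clouds(upright_pose(22.0, 2.0, -1.0), spec)
        # nothing below the mounting plane
        assert geo.union_cloud[:, 2].min() >= -1e-9
        # cylinder axis vertical through the projected carrier origin
        cyl_xy = geo.cylinder_cloud[:, :2]
        assert np.allclose(cyl_xy.mean(axis=0), [2.0, -1.0], atol=0.05)
        assert np.hypot(*(cyl_xy - [2.0, -1.0]).T).max() <= spec.cylinder_radius + 1e-9
        # connector interface plane: top layer centroid at the carrier origin
        top = geo.connector_cloud[np.abs(geo.connector_cloud[:, 2] - 22.0) < 1e-9]
        assert np.allclose(top.mean(axis=0), [2.0, -1.0, 22.0], atol=spec.cloud_pitch)

    def test_connector_edges_follow_carrier_axes(self):
        spec = PSABuildSpec(cloud_pitch=PITCH)
        pose = tilted_pose(30.0)
        geo = generate_submodel_clouds(pose, spec)
        local = (geo.connector_cloud - pose.translation) @ pose.rotation
        fx, fy = spec.brick_interface_footprint
        assert np.abs(local[:, 0]).max() <= fx / 2 + 1e-9
        assert np.abs(local[:, 1]).max() <= fy / 2 + 1e-9
        assert local[:, 2].min() >= -spec.connector_height - 1e-9

    def test_maximum_tested_tilt_succeeds(self):
        geo = generate_submodel_clouds(tilted_pose(40.0), PSABuildSpec(cloud_pitch=PITCH))
        assert len(geo.union_cloud) > 0

    def test_excessive_tilt_is_infeasible(self):
        with pytest.raises(WorkspaceInfeasibleError):
            generate_submodel_clouds(tilted_pose(60.0), PSABuildSpec(cloud_pitch=PITCH))

    def test_connector_through_base_is_collision(self):
        with pytest.raises(CollisionError):
            generate_submodel_clouds(upright_pose(height=8.0), PSABuildSpec(cloud_pitch=PITCH))

    def test_mirrored_pose_gives_mirrored_mesh(self):
        """No handedness bias: x -> -x reflected builds match within the pitch."""
        spec = PSABuildSpec(cloud_pitch=PITCH)
        pose = upright_pose(22.0, x=4.0)
        mirrored = upright_pose(22.0, x=-4.0)
        mesh_a = solidify(generate_submodel_clouds(pose, spec)).mesh
        mesh_b = solidify(generate_submodel_clouds(mirrored, spec)).mesh
        reflected = mesh_b.vertices * [-1.0, 1.0, 1.0]
        d, _ = cKDTree(mesh_a.vertices).query(reflected)
        assert d.max() <= spec.cloud_pitch


class TestFeasibility:
    def test_identity_pose_feasible(self):
        report = check_feasibility(upright_pose(), PSABuildSpec())
        assert report.feasible and report.tilt_deg == pytest.approx(0.0, abs=1e-9)

    def test_tilt_at_limit_reported(self):
        report = check_feasibility(tilted_pose(40.0), PSABuildSpec())
        assert report.feasible
        assert report.tilt_deg == pytest.approx(40.0, abs=1e-9)

    def test_connector_below_base_flags_collision(self):
        report = check_feasibility(upright_pose(height=7.0), PSABuildSpec())
        assert report.collision and not report.feasible
        assert any("below the base top" in r for r in report.reasons)

    def test_lateral_offset_limit(self):
        report = check_feasibility(upright_pose(22.0, x=20.0), PSABuildSpec())
        assert not report.offset_ok and not report.feasible


class TestSolidifyAndInterface:
    def test_psa_mesh_volume_near_analytic_union(self):
        """Alpha-shape volume within 20% of the parametric solids' union."""
        spec = PSABuildSpec(cloud_pitch=PITCH)
        pose = upright_pose(22.0)
        geo = solidify(generate_submodel_clouds(pose, spec))
        length, width, height = spec.base_size
        d = spec.chamfer_depth
        base_vol = length * width * height - 0.5 * d * d * length
        fx, fy = spec.brick_interface_footprint
        conn_vol = fx * fy * spec.connector_height
        cyl_len = (pose.translation[2] - 1.0 - spec.connector_height) - height
        cyl_vol = np.pi * spec.cylinder_radius**2 * cyl_len
        analytic = base_vol + conn_vol + cyl_vol
        assert 0.8 * analytic <= geo.mesh.volume <= 1.2 * analytic

    def test_interface_refit_recovers_pose(self, rng):
        spec = PSABuildSpec(cloud_pitch=PITCH)
        for pose in sample_feasible_poses(3, rng, spec, (5.0, 35.0)):
            mesh = solidify(generate_submodel_clouds(pose, spec)).mesh
            est = fit_interface_frame(mesh, pose, spec)
            rel = est.rotation.T @ pose.rotation
            ang = np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
            assert ang <= 0.5
            assert np.linalg.norm(est.translation - pose.translation) <= 1.5 * spec.cloud_pitch


class TestExportStl:
    def test_unit_cube_round_trip(self, tmp_path):
        mesh = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
        path = tmp_path / "cube.stl"
        export_stl(mesh, path, format="binary")
        back = trimesh.load(str(path))
        assert len(back.faces) == 12
        assert path.stat().st_size == 84 + 50 * 12
        d, _ = cKDTree(mesh.vertices).query(back.vertices)
        assert d.max() <= 1e-6

    def test_ascii_round_trip(self, tmp_path):
        mesh = trimesh.creation.box(extents=[2.0, 1.0, 1.0])
        path = tmp_path / "box.stl"
        export_stl(mesh, path, format="ascii")
        assert path.read_text().startswith("solid")
        back = trimesh.load(str(path))
        assert back.volume == pytest.approx(2.0, abs=1e-4)

    def test_face_normals_consistent_with_winding(self, tmp_path):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        path = tmp_path / "sphere.stl"
        export_stl(mesh, path)
        back = trimesh.load(str(path))
        assert back.is_watertight
        assert back.volume == pytest.approx(mesh.volume, rel=1e-5)

    def test_open_mesh_refused(self, tmp_path):
        mesh = trimesh.creation.box(extents=[1, 1, 1])
        open_mesh = trimesh.Trimesh(mesh.vertices, mesh.faces[:-1], process=False)
        with pytest.raises(MeshNotWatertightError):
            export_stl(open_mesh, tmp_path / "bad.stl")

    def test_unknown_format_rejected(self, tmp_path):
        mesh = trimesh.creation.box(extents=[1, 1, 1])
        with pytest.raises(ValidationError):
            export_stl(mesh, tmp_path / "x.stl", format="step")


class TestBuildSpecValidation:
    def test_fit_offset_range_enforced(self):
        with pytest.raises(ValidationError):
            PSABuildSpec(fit_offset=0.2)

    def test_alpha_below_pitch_rejected(self):
        with pytest.raises(ValidationError):
            PSABuildSpec(cloud_pitch=0.5, alpha_radius=0.3)
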