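"""Accuracy metric definitions and the Monte-Carlo propagation driver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psaforge.errors import ValidationError
from psaforge.frames import (
    FRAME_BASE,
    FRAME_RSC,
    FRAME_TRAJ,
    RigidTransform,
    compose,
    random_rigid_transform,
)
from psaforge.metrics import (
    AccuracyReport,
    NoiseConfig,
    angular_deviation,
    evaluate_case,
    offset_at_round_window,
    run_error_propagation,
)
from psaforge.registration import CalibrationModel, compute_psa_pose


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestAngularDeviation:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0, 1), (0, 0, 1), 0.0),
            ((0, 0, 1), (0, 1, 0), 90.0),
            ((0, 0, 1), (0, np.sin(np.radians(1)), np.cos(np.radians(1))), 1.0),
            ((0, 0, 1), (0, 0, -1), 180.0),  # oriented axes: no folding
        ],
    )
    def test_analytic_cases(self, a, b, expected):
        assert angular_deviation(a, b) == pytest.approx(expected, abs=1e-9)

    def test_normalizes_inputs(self):
        assert angular_deviation((0, 0, 5), (0, 0, 0.1)) == pytest.approx(0.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            angular_deviation((0, 0, 0), (0, 0, 1))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=100_000))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (unit(rng.normal(size=3)) for _ in range(3))
        assert angular_deviation(a, b) == pytest.approx(angular_deviation(b, a), abs=1e-12)
        assert angular_deviation(a, c) <= (
            angular_deviation(a, b) + angular_deviation(b, c) + 1e-9
        )


class TestOffsetAtRoundWindow:
    def test_coincident_axes_zero(self):
        assert offset_at_round_window(
            [0, 0, 0], [0, 0, 1], [0, 0, -5], [0, 0, 1]
        ) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_axes_offset(self):
        """Parallel lateral shift equals the worst bench offset magnitude, 0.38 mm."""
        off = offset_at_round_window(
            [0, 0, 10], [0, 0, 1], [0.38, 0, -3], [0, 0, 1]
        )
        assert off == pytest.approx(0.38, abs=1e-12)

    def test_achieved_axis_parallel_to_plane_rejected(self):
        with pytest.raises(ValidationError):
            offset_at_round_window([0, 0, 0], [0, 0, 1], [1, 0, 0], [1, 0, 0])

    def test_rw_point_off_planned_axis_rejected(self):
        with pytest.raises(ValidationError):
            offset_at_round_window(
                [0, 0, 0], [0, 0, 1], [1, 0, 0], [0, 0, 1], rw_point=[5, 0, 0]
            )

    def test_matches_dense_line_sampling_oracle(self, rng):
        """Oracle: sample the achieved axis, bracket the plane crossing, refine linearly."""
        for _ in range(30):
            d0 = unit(rng.normal(size=3))
            p0 = rng.uniform(-10, 10, 3)
            rw = p0 + rng.uniform(-5, 5) * d0
            q0 = rng.uniform(-10, 10, 3)
            d1 = unit(d0 + 0.3 * rng.normal(size=3))
            ts = np.linspace(-200.0, 200.0, 400_001)
            f = (q0[None] + ts[:, None] * d1[None] - rw) @ d0  # signed plane distance
            k = np.flatnonzero(np.signbit(f[:-1]) != np.signbit(f[1:]))[0]
            t_star = ts[k] - f[k] * (ts[k + 1] - ts[k]) / (f[k + 1] - f[k])
            expected = np.linalg.norm(q0 + t_star * d1 - rw)
            got = offset_at_round_window(p0, d0, q0, d1, rw_point=rw)
            assert abs(got - expected) <= 1e-9


def simple_scene():
    """Trajectory along +z in the carrier, entry point 10 mm above its origin."""
    rsc_to_traj = RigidTransform.translation_only([0, 0, 10], FRAME_TRAJ, FRAME_RSC)
    calibration = CalibrationModel(
        RigidTransform.identity().relabel(FRAME_TRAJ, FRAME_BASE)
    )
    pose = compute_psa_pose(calibration, rsc_to_traj)
    return rsc_to_traj, calibration, pose


class TestEvaluateCase:
    def test_zero_perturbation_closes_the_loop(self):
        rsc_to_traj, calibration, pose = simple_scene()
        report = evaluate_case(rsc_to_traj, calibration, pose)
        assert report.angular_deviation_deg <= 1e-9
        assert report.rw_offset_mm <= 1e-9

    def test_pure_rotation_about_rw_point(self):
        """0.5 deg tilt about the entry point: angular error only, zero offset."""
        rsc_to_traj, calibration, pose = simple_scene()
        rw_rsc = [0.0, 0.0, 10.0]
        perturb = compose(
            RigidTransform.translation_only(rw_rsc, FRAME_RSC, FRAME_RSC),
            compose(
                RigidTransform.from_rotvec([0.5, 0, 0], from_frame=FRAME_RSC, to_frame=FRAME_RSC),
                RigidTransform.translation_only(-np.asarray(rw_rsc), FRAME_RSC, FRAME_RSC),
            ),
        )
        report = evaluate_case(rsc_to_traj, calibration, pose, perturb)
        assert report.angular_deviation_deg == pytest.approx(0.5, abs=1e-9)
        assert report.rw_offset_mm <= 1e-9

    @pytest.mark.parametrize("angle", [0.5, 1.0, 5.0])
    def test_rotation_about_rw_never_offsets(self, angle, rng):
        rsc_to_traj, calibration, pose = simple_scene()
        rw_rsc = np.array([0.0, 0.0, 10.0])
        axis = rng.normal(size=3)
        axis = angle * axis / np.linalg.norm(axis)
        perturb = compose(
            RigidTransform.translation_only(rw_rsc, FRAME_RSC, FRAME_RSC),
            compose(
                RigidTransform.from_rotvec(axis, from_frame=FRAME_RSC, to_frame=FRAME_RSC),
                RigidTransform.translation_only(-rw_rsc, FRAME_RSC, FRAME_RSC),
            ),
        )
        report = evaluate_case(rsc_to_traj, calibration, pose, perturb)
        assert report.rw_offset_mm <= 1e-9

    def test_pure_lateral_translation(self):
        """0.2 mm shift orthogonal to the trajectory: offset only, zero angle."""
        rsc_to_traj, calibration, pose = simple_scene()
        perturb = RigidTransform.translation_only([0.2, 0, 0], FRAME_RSC, FRAME_RSC)
        report = evaluate_case(rsc_to_traj, calibration, pose, perturb)
        assert report.rw_offset_mm == pytest.approx(0.2, abs=1e-9)
        assert report.angular_deviation_deg <= 1e-9

    def test_invariant_under_common_base_reexpression(self, rng):
        """Metrics are scalars: re-expressing CS_BASE changes nothing."""
        rsc_to_traj, calibration, pose = simple_scene()
        perturb = RigidTransform.from_rotvec(
            [0.3, -0.2, 0.1], [0.05, 0.1, -0.02], FRAME_RSC, FRAME_RSC
        )
        ref = evaluate_case(rsc_to_traj, calibration, pose, perturb)
        for _ in range(10):
            g = random_rigid_transform(rng, from_frame=FRAME_BASE, to_frame=FRAME_BASE)
            cal2 = CalibrationModel(
                compose(g, calibration.base_to_traj).relabel(FRAME_TRAJ, FRAME_BASE)
            )
            pose2 = compose(g, pose).relabel(FRAME_RSC, FRAME_BASE)
            out = evaluate_case(rsc_to_traj, cal2, pose2, perturb)
            assert out.angular_deviation_deg == pytest.approx(
                ref.angular_deviation_deg, abs=1e-10
            )
            assert out.rw_offset_mm == pytest.approx(ref.rw_offset_mm, abs=1e-10)


class TestAccuracyReportValidation:
    def test_angle_bounds(self):
        with pytest.raises(ValidationError):
            AccuracyReport("x", 200.0, 0.0)

    def test_offset_sign(self):
        with pytest.raises(ValidationError):
            AccuracyReport("x", 0.0, -0.1)


class TestRunErrorPropagation:
    @staticmethod
    def _zero_factory(rng, i):
        return AccuracyReport(f"t{i}", 0.0, 0.0, 0.0)

    def test_zero_noise_gives_all_zero_reports(self):
        frame, summary = run_error_propagation(self._zero_factory, 10, seed=1)
        assert (frame["Angular deviation [deg]"] == 0).all()
        assert summary["Euclidean distance [mm]"]["mean"] == 0.0

    def test_same_seed_is_bit_identical(self):
        def factory(rng, i):
            v = rng.normal()
            return AccuracyReport(f"t{i}", abs(v), abs(v) / 2, 0.01)

        f1, s1 = run_error_propagation(factory, 50, seed=7)
        f2, s2 = run_error_propagation(factory, 50, seed=7)
        assert f1.equals(f2)
        assert s1 == s2

    def test_invalid_trial_count_rejected(self):
        with pytest.raises(ValidationError):
            run_error_propagation(self._zero_factory, 0, seed=1)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            NoiseConfig(fle_sigma=-0.1)
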