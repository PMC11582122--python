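"""End-to-end orchestration: registration -> planning -> pose -> solid.

This is the programmatic core behind the CLI: it runs the image-to-carrier
registration, carries the planning points into carrier coordinates, builds
the trajectory frame, computes the adapter pose with calibration
compensation, checks workspace feasibility, and (for builds) samples and
solidifies the adapter geometry. The same entry points drive the Monte-Carlo
error-propagation study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import __version__
from .casefile import LoadedCase
from .frames import RigidTransform
from .geometry import (
    FeasibilityReport,
    PSABuildSpec,
    PSAGeometry,
    check_feasibility,
    generate_submodel_clouds,
    solidify,
)
from .metrics import AccuracyReport, NoiseConfig, evaluate_case
from .planning import build_trajectory_frame, map_planning_to_rsc
from .registration import RegistrationResult, compute_psa_pose, register_fiducials
from .synthetic import FixtureLayout, SpiralCochleaParams, make_case, perturb_measurements

__all__ = ["PoseResult", "BuildResult", "compute_pose_for_case", "build_adapter",
           "make_simulation_scene_factory"]


@dataclass(frozen=True)
class PoseResult:
    """Everything the pose computation yields before any geometry is built."""

    registration: RegistrationResult
    rsc_to_traj: RigidTransform
    pose: RigidTransform  # BASE <- RSC
    feasibility: FeasibilityReport
    predicted: AccuracyReport  # noise-free prediction; zero by construction


@dataclass(frozen=True)
class BuildResult:
    pose_result: PoseResult
    geometry: PSAGeometry  # includes the solidified mesh

    @property
    def mesh(self):
        return self.geometry.mesh


def compute_pose_for_case(case: LoadedCase) -> PoseResult:
    """Registration through pose computation and feasibility, no meshing."""
    reg = register_fiducials(case.fiducials_img, case.fiducials_rsc)
    pts_rsc = map_planning_to_rsc(case.planning_img, reg)
    rsc_to_traj = build_trajectory_frame(pts_rsc).pose
    pose = compute_psa_pose(case.calibration, rsc_to_traj)
    feasibility = check_feasibility(pose, case.spec)
    predicted = evaluate_case(
        rsc_to_traj, case.calibration, pose, case_id=case.case_id, fre_mm=reg.fre
    )
    return PoseResult(reg, rsc_to_traj, pose, feasibility, predicted)


def build_adapter(case: LoadedCase) -> BuildResult:
    """Full build: pose computation plus solidified adapter geometry."""
    pose_result = compute_pose_for_case(case)
    geometry = generate_submodel_clouds(pose_result.pose, case.spec)
    geometry = solidify(geometry)
    return BuildResult(pose_result, geometry)


def pose_report_dict(case: LoadedCase, result: PoseResult) -> dict:
    """JSON-ready pose report with full provenance."""
    reg = result.registration
    feas = result.feasibility
    return {
        "tool": {"name": "psaforge", "version": __version__},
        "input": {"case_id": case.case_id, "sha256": case.source_sha256, "seed": case.seed},
        "pose_base_from_rsc": result.pose.matrix.tolist(),
        "registration": {
            "fre_mm": reg.fre,
            "residuals_mm": {lab: float(r) for lab, r in zip(reg.labels, reg.residuals)},
        },
        "feasibility": {
            "feasible": feas.feasible,
            "tilt_deg": feas.tilt_deg,
            "lateral_offset_mm": feas.lateral_offset_mm,
            "connector_height_mm": feas.connector_height_mm,
            "connector_clearance_mm": feas.connector_clearance_mm,
            "collision": feas.collision,
            "reasons": list(feas.reasons),
        },
        "predicted_accuracy": {
            "angular_deviation_deg": result.predicted.angular_deviation_deg,
            "rw_offset_mm": result.predicted.rw_offset_mm,
        },
    }


def make_simulation_scene_factory(
    noise: NoiseConfig,
    cochlea: SpiralCochleaParams | None = None,
    layout: FixtureLayout | None = None,
    tilt_range: tuple[float, float] = (0.0, 35.0),
    spec: PSABuildSpec | None = None,
):
    """Scene factory for :func:`psaforge.metrics.run_error_propagation`.

    Each trial generates a fresh synthetic specimen, overlays the configured
    noise, runs the real pipeline (registration, frame construction, pose
    computation) on the noisy observations, and scores the result against
    the trial's own ground-truth calibration under the drawn mounting error.
    """
    cochlea = cochlea or SpiralCochleaParams()
    layout = layout or FixtureLayout()
    spec = spec or PSABuildSpec()

    def factory(rng: np.random.Generator, trial: int) -> AccuracyReport:
        case_seed = int(rng.integers(0, 2**31 - 1))
        case = make_case(
            cochlea=cochlea, layout=layout, seed=case_seed,
            tilt_range=tilt_range, build_spec=spec,
            case_id=f"trial-{trial:05d}",
        )
        case = perturb_measurements(
            case,
            fle_sigma=noise.fle_sigma,
            print_sigma_rot=noise.print_sigma_rot,
            print_sigma_trans=noise.print_sigma_trans,
            seat_sigma_rot=noise.seat_sigma_rot,
            seat_sigma_trans=noise.seat_sigma_trans,
            rng=rng,
        )
        reg = register_fiducials(case.fiducials_img, case.fiducials_rsc)
        pts_rsc = map_planning_to_rsc(case.planning_img, reg)
        rsc_to_traj = build_trajectory_frame(pts_rsc).pose
        pose = compute_psa_pose(case.calibration, rsc_to_traj)
        return evaluate_case(
            case.true_rsc_to_traj,
            case.calibration,
            pose,
            mount_perturbation=case.mount_perturbation,
            case_id=case.case_id,
            fre_mm=reg.fre,
        )

    return factory
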