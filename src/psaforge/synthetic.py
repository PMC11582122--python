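"""Synthetic stand-ins for the physical workflow.

Everything the bench workflow would obtain from dissection, CBCT scanning
and bench calibration is generated here: a parametric spiral cochlea that
yields plausible planning points, a carrier fiducial layout, the image-space
observations of both under a random image pose, a bench calibration, and
partial-volume renderings of the markers at CT-like voxel sizes. Ground
truth is retained alongside every observation so recovery can be tested.

The cochlea model is a planar logarithmic spiral scaled so its footprint
matches the basal-turn length (A) and width (B) measures, lifted with a
constant helical pitch; porcine defaults (A = 7.31 mm, B = 5.30 mm, 3.5
turns) reflect measured specimens, versus roughly A 8.4-9.2 mm, B 6.2-7.0 mm
and 2.5 turns in humans. Only this geometric envelope matters for
planning-point plausibility; no anatomical detail is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError, WorkspaceInfeasibleError
from .frames import (
    FRAME_BASE,
    FRAME_IMG,
    FRAME_RSC,
    FRAME_TRAJ,
    RigidTransform,
    compose,
    invert,
)
from .geometry import PSABuildSpec, check_feasibility
from .planning import PlanningPoints, VoxelVolume, build_trajectory_frame
from .registration import CalibrationModel, FiducialSet, canonical_fiducial_order
from .registration import compute_psa_pose

__all__ = [
    "SpiralCochleaParams",
    "FixtureLayout",
    "SyntheticCase",
    "spiral_planning_points",
    "make_case",
    "perturb_measurements",
    "render_fiducial_volume",
]

#: ideal bench calibration: trajectory entry point 32 mm above the base,
#: insertion axis pointing straight down (the tool descends onto the specimen)
BENCH_TARGET_HEIGHT = 32.0
_IDEAL_CAL_ROTATION = np.diag([1.0, -1.0, -1.0])  # TRAJ z -> bench -z


@dataclass(frozen=True)
class SpiralCochleaParams:
    """Envelope parameters of the synthetic cochlea (mm / turns)."""

    a_value: float = 7.31  # basal-turn length measure
    b_value: float = 5.30  # basal-turn width measure
    side: str = "right"
    turns: float = 3.5
    helix_pitch: float = 1.0  # mm of axial rise per turn
    decay: float = 0.12  # radial decay rate of the log spiral, 1/rad

    def __post_init__(self):
        if not self.a_value > self.b_value > 0:
            raise ValidationError(
                f"need A > B > 0, got A={self.a_value}, B={self.b_value}"
            )
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.turns <= 1.0:
            raise ValidationError("need more than one turn")


@dataclass(frozen=True)
class FixtureLayout:
    """Carrier fiducial layout: four sphere centers in carrier coordinates.

    The stock layout spans > 20 mm, is non-coplanar by > 2 mm, keeps every
    pair > 10 mm apart and has distinct centroid distances so the canonical
    ordering is unambiguous. Sphere radius 2.5 mm (5 mm titanium spheres).
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [16.0, 0.0, 0.0],
                [-14.0, 10.0, 1.0],
                [-10.0, -14.0, 3.0],
                [4.0, 5.0, 12.0],
            ]
        )
    )
    sphere_radius: float = 2.5

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        if centers.shape != (4, 3):
            raise ValidationError("layout must contain exactly 4 sphere centers")
        diff = centers[:, None] - centers[None, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 10.0:
            raise ValidationError(
                f"fiducial spacing {dist.min():.1f} mm < 10 mm minimum"
            )
        centered = centers - centers.mean(axis=0)
        # distance of the farthest point from the best-fit plane
        _, _, vt = np.linalg.svd(centered)
        plane_dev = np.abs(centered @ vt[2])
        if plane_dev.max() < 2.0:
            raise ValidationError("fiducial layout must be non-coplanar by >= 2 mm")
        centers = centers.copy()
        centers.flags.writeable = False
        object.__setattr__(self, "centers", centers)

    def as_fiducial_set(self) -> FiducialSet:
        order = canonical_fiducial_order(self.centers)
        labels = tuple(f"F{i + 1}" for i in range(len(self.centers)))
        return FiducialSet(labels, self.centers[order], FRAME_RSC)


@dataclass(frozen=True)
class SyntheticCase:
    """One fully specified virtual specimen: observations plus ground truth."""

    case_id: str
    side: str
    seed: int
    cochlea: SpiralCochleaParams
    layout: FixtureLayout
    fiducials_rsc: FiducialSet  # measured carrier markers (exact)
    fiducials_img: FiducialSet  # markers observed in image space
    planning_img: PlanningPoints  # planning points picked in image space
    calibration: CalibrationModel
    # ground truth, not available to the pipeline in a real experiment:
    true_img_to_rsc: RigidTransform
    true_planning_rsc: PlanningPoints
    true_rsc_to_traj: RigidTransform
    true_pose: RigidTransform  # BASE <- RSC
    mount_perturbation: RigidTransform | None = None


def spiral_planning_points(params: SpiralCochleaParams) -> PlanningPoints:
    """Planning points on the synthetic spiral, in the cochlea's own frame.

    The spiral lies in the local x-y plane, starting wide at the basal
    opening and decaying inward over ``turns`` revolutions while rising with
    constant pitch. P1 sits at the basal opening (the round-window stand-in),
    P2 is 3 mm along the spiral tangent there (the direction a tangentially
    inserted electrode travels), and P3 sits three quarters around the first
    turn. The left side is the mirror image of the right.
    """
    phi_max = 2.0 * np.pi * params.turns
    phi = np.linspace(0.0, phi_max, 1024)
    r = np.exp(-params.decay * phi)
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    # scale the raw footprint to the A (length) x B (width) envelope
    sx = params.a_value / (x.max() - x.min())
    sy = params.b_value / (y.max() - y.min())

    def at(p):
        rr = np.exp(-params.decay * p)
        return np.array(
            [sx * rr * np.cos(p), sy * rr * np.sin(p), params.helix_pitch * p / (2 * np.pi)]
        )

    def tangent(p):
        rr = np.exp(-params.decay * p)
        dx = sx * rr * (-params.decay * np.cos(p) - np.sin(p))
        dy = sy * rr * (-params.decay * np.sin(p) + np.cos(p))
        dz = params.helix_pitch / (2 * np.pi)
        t = np.array([dx, dy, dz])
        return t / np.linalg.norm(t)

    p1 = at(0.0)
    p2 = p1 + 3.0 * tangent(0.0)
    p3 = at(1.5 * np.pi)
    pts = np.stack([p1, p2, p3])
    if params.side == "left":
        pts = pts * np.array([1.0, -1.0, 1.0])
    return PlanningPoints(pts[0], pts[1], pts[2], frame="COCHLEA")


def _pose_cochlea_into_rsc(
    pts: PlanningPoints,
    tilt_deg: float,
    azimuth_deg: float,
    roll_deg: float,
    p1_target: np.ndarray,
) -> PlanningPoints:
    """Rigidly place the cochlea on the carrier with a prescribed insertion tilt.

    The point set is rotated so the trajectory direction P1->P2 points
    downward (into the specimen, toward the carrier) tilted ``tilt_deg`` from
    vertical about a horizontal axis at ``azimuth_deg``, with ``roll_deg`` of
    spin about the trajectory; P1 lands at ``p1_target``.
    """
    z = pts.p2 - pts.p1
    z = z / np.linalg.norm(z)
    u = (pts.p3 - pts.p1) - np.dot(pts.p3 - pts.p1, z) * z
    u = u / np.linalg.norm(u)
    v = np.cross(z, u)
    basis = np.column_stack([u, v, z])  # cochlea-frame trajectory basis
    tilt_axis = np.array(
        [np.cos(np.radians(azimuth_deg)), np.sin(np.radians(azimuth_deg)), 0.0]
    )
    r_tilt = Rotation.from_rotvec(tilt_axis * np.radians(tilt_deg)).as_matrix()
    r_roll = Rotation.from_rotvec([0.0, 0.0, np.radians(roll_deg)]).as_matrix()
    target_basis = r_tilt @ r_roll @ _IDEAL_CAL_ROTATION  # z -> tilted downward
    rot = target_basis @ basis.T
    arr = (pts.as_array() - pts.p1) @ rot.T + np.asarray(p1_target, dtype=float)
    return PlanningPoints(arr[0], arr[1], arr[2], frame=FRAME_RSC)


def _small_rigid(rng, sigma_rot_deg: float, sigma_trans: float, frame: str):
    rotvec = rng.normal(0.0, max(sigma_rot_deg, 0.0), 3)
    trans = rng.normal(0.0, max(sigma_trans, 0.0), 3)
    return RigidTransform.from_rotvec(rotvec, trans, from_frame=frame, to_frame=frame)


def make_case(
    cochlea: SpiralCochleaParams | None = None,
    layout: FixtureLayout | None = None,
    seed: int = 0,
    tilt_range: tuple[float, float] = (0.0, 35.0),
    cal_sigma_rot: float = 0.2,
    cal_sigma_trans: float = 0.1,
    build_spec: PSABuildSpec | None = None,
    case_id: str | None = None,
) -> SyntheticCase:
    """Generate one synthetic specimen case, observations plus ground truth.

    The specimen placement (tilt, spin, position on the carrier) and the
    image pose are drawn from ``seed``; placements whose computed adapter
    pose falls outside the buildable workspace are rejected and redrawn, as
    an experimenter would re-glue an awkwardly oriented specimen. The bench
    calibration is the ideal head-down target pose composed with a small
    random deviation (the imperfection the calibration matrix exists to
    compensate). Identical seeds regenerate the case bit-identically; left
    and right sides are exact mirror images.
    """
    cochlea = cochlea or SpiralCochleaParams()
    layout = layout or FixtureLayout()
    spec = build_spec or PSABuildSpec()
    rng = np.random.default_rng(seed)
    fiducials_rsc = layout.as_fiducial_set()

    # mirror at the end keeps left/right draws identical
    base_pts = spiral_planning_points(replace(cochlea, side="right"))

    cal_dev = _small_rigid(rng, cal_sigma_rot, cal_sigma_trans, "?")
    cal_rotation = cal_dev.rotation @ _IDEAL_CAL_ROTATION
    cal_translation = np.array([0.0, 0.0, BENCH_TARGET_HEIGHT]) + cal_dev.translation
    calibration = CalibrationModel(
        RigidTransform(
            cal_rotation, cal_translation, from_frame=FRAME_TRAJ, to_frame=FRAME_BASE
        ),
        notes=f"synthetic bench calibration, seed {seed}",
    )

    planning_rsc = None
    for _ in range(200):
        tilt = rng.uniform(*tilt_range)
        azimuth = rng.uniform(0.0, 360.0)
        roll = rng.uniform(0.0, 360.0)
        p1_target = np.array(
            [rng.uniform(-3.0, 3.0), rng.uniform(-3.0, 3.0), rng.uniform(10.0, 14.0)]
        )
        candidate = _pose_cochlea_into_rsc(base_pts, tilt, azimuth, roll, p1_target)
        pose = compute_psa_pose(
            calibration, build_trajectory_frame(candidate).pose
        )
        if check_feasibility(pose, spec).feasible:
            planning_rsc = candidate
            break
    if planning_rsc is None:
        raise WorkspaceInfeasibleError(
            "no feasible specimen placement found for this layout/spec"
        )
    if cochlea.side == "left":
        arr = planning_rsc.as_array() * np.array([1.0, -1.0, 1.0])
        planning_rsc = PlanningPoints(arr[0], arr[1], arr[2], frame=FRAME_RSC)

    rsc_to_traj = build_trajectory_frame(planning_rsc).pose
    true_pose = compute_psa_pose(calibration, rsc_to_traj)

    # image pose: where the carrier sits in scanner coordinates
    rot = Rotation.random(rng=rng).as_matrix()
    img_to_rsc = RigidTransform(
        rot, rng.uniform(-20.0, 20.0, 3), from_frame=FRAME_IMG, to_frame=FRAME_RSC
    )
    rsc_to_img = invert(img_to_rsc)
    fiducials_img = FiducialSet(
        fiducials_rsc.labels, rsc_to_img.apply(fiducials_rsc.centers), FRAME_IMG
    )
    planning_img = PlanningPoints(
        rsc_to_img.apply(planning_rsc.p1),
        rsc_to_img.apply(planning_rsc.p2),
        rsc_to_img.apply(planning_rsc.p3),
        frame=FRAME_IMG,
    )
    return SyntheticCase(
        case_id=case_id or f"synthetic-{seed:05d}",
        side=cochlea.side,
        seed=seed,
        cochlea=cochlea,
        layout=layout,
        fiducials_rsc=fiducials_rsc,
        fiducials_img=fiducials_img,
        planning_img=planning_img,
        calibration=calibration,
        true_img_to_rsc=img_to_rsc,
        true_planning_rsc=planning_rsc,
        true_rsc_to_traj=rsc_to_traj,
        true_pose=true_pose,
    )


def perturb_measurements(
    case: SyntheticCase,
    fle_sigma: float = 0.0,
    print_sigma_rot: float = 0.0,
    print_sigma_trans: float = 0.0,
    seat_sigma_rot: float = 0.0,
    seat_sigma_trans: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> SyntheticCase:
    """Overlay measurement and mounting noise on a clean case.

    Adds i.i.d. zero-mean Gaussian noise (SD ``fle_sigma`` per coordinate) to
    the image-space fiducials, and composes a small random rigid mount
    perturbation in carrier coordinates from the print and seating error
    magnitudes. With all sigmas zero the case is returned unchanged. Ground
    truth fields are retained for recovery tests.
    """
    for name, v in [
        ("fle_sigma", fle_sigma),
        ("print_sigma_rot", print_sigma_rot),
        ("print_sigma_trans", print_sigma_trans),
        ("seat_sigma_rot", seat_sigma_rot),
        ("seat_sigma_trans", seat_sigma_trans),
    ]:
        if v < 0:
            raise ValidationError(f"{name} must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    noisy_fid = FiducialSet(
        case.fiducials_img.labels,
        case.fiducials_img.centers + rng.normal(0.0, fle_sigma, (len(case.fiducials_img), 3))
        if fle_sigma > 0
        else case.fiducials_img.centers,
        case.fiducials_img.frame,
    )
    if max(print_sigma_rot, print_sigma_trans, seat_sigma_rot, seat_sigma_trans) > 0:
        perturbation = compose(
            _small_rigid(rng, print_sigma_rot, print_sigma_trans, FRAME_RSC),
            _small_rigid(rng, seat_sigma_rot, seat_sigma_trans, FRAME_RSC),
        )
    else:
        perturbation = None
    return replace(case, fiducials_img=noisy_fid, mount_perturbation=perturbation)


def render_fiducial_volume(
    layout: FixtureLayout,
    rsc_to_img: RigidTransform | None = None,
    spacing: float = 0.3,
    margin: float = 3.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    supersample: int = 5,
) -> tuple[VoxelVolume, FiducialSet]:
    """Rasterize the carrier spheres into a voxel volume (image frame).

    Voxel intensities are the occupied volume fraction of each voxel,
    estimated by ``supersample``^3 midpoint subsamples, emulating the
    partial-volume effect a CT reconstruction shows at the sphere rim;
    optional Gaussian intensity noise on top. Returns the volume together
    with the ground-truth centers in the image frame (canonical order).
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    centers = (
        layout.centers if rsc_to_img is None else rsc_to_img.apply(layout.centers)
    )
    radius = layout.sphere_radius
    lo = centers.min(axis=0) - radius - margin
    hi = centers.max(axis=0) + radius + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo
    data = np.zeros(shape)
    offsets = (np.arange(supersample) + 0.5) / supersample - 0.5  # voxel-relative
    sub = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), -1).reshape(-1, 3)
    sub_world = sub * spacing
    for c in centers:
        lo_idx = np.maximum(np.floor((c - origin - radius - spacing) / spacing), 0).astype(int)
        hi_idx = np.minimum(
            np.ceil((c - origin + radius + spacing) / spacing).astype(int) + 1, shape
        )
        idx = np.stack(
            np.meshgrid(*[np.arange(lo_idx[d], hi_idx[d]) for d in range(3)], indexing="ij"),
            -1,
        )
        voxel_centers = origin + idx * spacing
        d2 = ((voxel_centers[..., None, :] + sub_world - c) ** 2).sum(axis=-1)
        frac = (d2 <= radius**2).mean(axis=-1)
        data[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] += frac
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, data.shape)
    frame = FRAME_IMG if rsc_to_img is not None else FRAME_RSC
    order = canonical_fiducial_order(centers)
    labels = tuple(f"F{i + 1}" for i in range(len(centers)))
    truth = FiducialSet(labels, centers[order], frame)
    return VoxelVolume(data, np.full(3, spacing), origin), truth
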