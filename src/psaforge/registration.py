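"""Paired-point rigid registration and the adapter pose computation.

The carrier (RSC) holds four 5 mm titanium spheres whose centers are known
precisely in carrier coordinates. Locating the same spheres in the planning
image yields paired points; the least-squares rigid fit (SVD/Kabsch with the
sign correction that forbids reflections) gives the image-to-carrier
transform, and the RMS of the per-fiducial residuals is the fiducial
registration error (FRE).

The adapter pose itself is a one-line transform chain: given the bench
calibration pose of the target trajectory and the planned trajectory
expressed in carrier coordinates,

    base_T_rsc = base_T_traj · (rsc_T_traj)^-1

so that mounting the carrier at ``base_T_rsc`` places the planned trajectory
exactly on the calibrated insertion axis. The calibration matrix absorbs any
manufacturing deviation between the force-measurement axis and the insertion
tool axis, which the bench treats as one coaxial line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateGeometryError,
    FrameMismatchError,
    InsufficientFiducialsError,
    ValidationError,
)
from .frames import FRAME_BASE, FRAME_TRAJ, RigidTransform, compose, invert

__all__ = [
    "FiducialSet",
    "RegistrationResult",
    "CalibrationModel",
    "register_fiducials",
    "compute_fre",
    "compute_psa_pose",
    "canonical_fiducial_order",
]

#: second singular value of the centered point matrix below this means collinear
COLLINEARITY_TOL = 1e-6


@dataclass(frozen=True)
class FiducialSet:
    """Labeled marker centers in one frame.

    At least three non-collinear markers are required for a rigid fit.
    """

    labels: tuple[str, ...]
    centers: np.ndarray  # (N, 3) mm
    frame: str

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float)).copy()
        if centers.shape != (len(self.labels), 3):
            raise ValidationError(
                f"centers shape {centers.shape} does not match {len(self.labels)} labels"
            )
        if len(self.labels) != len(set(self.labels)):
            raise ValidationError("fiducial labels must be unique")
        if len(self.labels) < 3:
            raise InsufficientFiducialsError(
                f"need at least 3 fiducials, got {len(self.labels)}"
            )
        s = np.linalg.svd(centers - centers.mean(axis=0), compute_uv=False)
        if s[1] <= COLLINEARITY_TOL:
            raise DegenerateGeometryError(
                f"fiducials are collinear (second singular value {s[1]:.2e} mm)"
            )
        centers.flags.writeable = False
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self):
        return len(self.labels)

    def reorder(self, labels: tuple[str, ...]) -> "FiducialSet":
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise ValidationError(f"labels not present in set: {missing}")
        return FiducialSet(
            tuple(labels), self.centers[[index[lab] for lab in labels]], self.frame
        )


@dataclass(frozen=True)
class RegistrationResult:
    """Fitted transform plus per-fiducial residuals and their RMS (the FRE)."""

    transform: RigidTransform
    labels: tuple[str, ...]
    residuals: np.ndarray  # per-fiducial distances, mm
    fre: float  # mm, RMS of residuals

    def __post_init__(self):
        res = np.asarray(self.residuals, dtype=float).copy()
        res.flags.writeable = False
        object.__setattr__(self, "residuals", res)


@dataclass(frozen=True)
class CalibrationModel:
    """Bench calibration: the target trajectory pose expressed in CS_BASE.

    The z-axis of ``base_to_traj`` (third rotation column) is the insertion
    axis direction in base coordinates; its origin is where the planned entry
    point (round-window center) must land. Measured once per bench, e.g. on a
    coordinate measurement machine; consumed here as data.
    """

    base_to_traj: RigidTransform
    notes: str = ""

    def __post_init__(self):
        t = self.base_to_traj
        if t.to_frame != FRAME_BASE or t.from_frame != FRAME_TRAJ:
            raise FrameMismatchError(
                f"calibration must map TRAJ->BASE, got {t.to_frame}<-{t.from_frame}"
            )

    @property
    def insertion_axis_direction(self) -> np.ndarray:
        return self.base_to_traj.rotation[:, 2].copy()

    @property
    def target_entry_point(self) -> np.ndarray:
        return self.base_to_traj.translation.copy()


def _matched_centers(moving: FiducialSet, fixed: FiducialSet):
    common = [lab for lab in moving.labels if lab in set(fixed.labels)]
    if len(common) < 3:
        raise InsufficientFiducialsError(
            f"only {len(common)} common fiducial labels; need at least 3"
        )
    mov = moving.reorder(tuple(common)).centers
    fix = fixed.reorder(tuple(common)).centers
    return tuple(common), mov, fix


def register_fiducials(moving: FiducialSet, fixed: FiducialSet) -> RegistrationResult:
    """Least-squares rigid fit mapping ``moving`` onto ``fixed`` (Kabsch/SVD).

    Minimizes sum ||R m_i + t - f_i||^2 over proper rotations R and
    translations t; the determinant sign correction guarantees that no
    reflection is returned even for noisy near-planar marker layouts.
    Correspondence is by label; both sets must share >= 3 labels.
    """
    common, mov, fix = _matched_centers(moving, fixed)
    mov_mean = mov.mean(axis=0)
    fix_mean = fix.mean(axis=0)
    cov = (mov - mov_mean).T @ (fix - fix_mean)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fix_mean - rot @ mov_mean
    transform = RigidTransform(rot, trans, from_frame=moving.frame, to_frame=fixed.frame)
    residuals = np.linalg.norm(transform.apply(mov) - fix, axis=1)
    fre = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(transform, common, residuals, fre)


def compute_fre(t: RigidTransform, moving: FiducialSet, fixed: FiducialSet) -> float:
    """RMS distance between transformed moving fiducials and their fixed mates (mm)."""
    _, mov, fix = _matched_centers(moving, fixed)
    residuals = np.linalg.norm(t.apply(mov) - fix, axis=1)
    return float(np.sqrt(np.mean(residuals**2)))


def compute_psa_pose(
    calibration: CalibrationModel, rsc_to_traj: RigidTransform
) -> RigidTransform:
    """Adapter pose: base_T_rsc = base_T_traj · (rsc_T_traj)^-1.

    ``rsc_to_traj`` expresses the planned trajectory frame in carrier
    coordinates (RSC<-TRAJ); the result is the carrier pose in bench base
    coordinates (BASE<-RSC) that the adapter's two functional surfaces must
    realize.
    """
    if rsc_to_traj.from_frame != FRAME_TRAJ:
        raise FrameMismatchError(
            f"rsc_to_traj must map TRAJ into the carrier frame, got "
            f"{rsc_to_traj.to_frame}<-{rsc_to_traj.from_frame}"
        )
    return compose(calibration.base_to_traj, invert(rsc_to_traj))


def canonical_fiducial_order(centers: np.ndarray) -> np.ndarray:
    """Stable ordering key for unlabeled markers: distance from the marker
    centroid, ties broken lexicographically by coordinates.

    The centroid-distance key is invariant under rigid motion, so applying it
    in both the carrier frame and the image frame yields a consistent
    correspondence without manual labeling (provided the layout has distinct
    centroid distances, which the stock carrier layout does).
    Returns the argsort index array.
    """
    centers = np.asarray(centers, dtype=float)
    dist = np.linalg.norm(centers - centers.mean(axis=0), axis=1)
    # round to nm so genuinely tied distances fall through to the lex key
    key = np.round(dist, 6)
    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0], key))
    return order
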