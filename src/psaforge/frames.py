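"""Labeled rigid-transform algebra.

All poses in the pipeline are proper rigid transforms between explicitly
labeled coordinate systems:

* ``BASE`` — the test-bench base (force-sensor side),
* ``RSC``  — the registration and specimen carrier,
* ``TRAJ`` — the planned insertion trajectory,
* ``IMG``  — the volumetric image (CBCT) space.

A :class:`RigidTransform` maps point coordinates expressed in ``from_frame``
into ``to_frame``; the pose written :math:`^{A}T_{B}` in the usual
superscript/subscript notation has ``to_frame="A"``, ``from_frame="B"``.
Frame labels are checked at composition time, which turns the classic
inverted-transform bug into an immediate, explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import polar
from scipy.spatial.transform import Rotation

from .errors import FrameMismatchError, ValidationError

__all__ = [
    "FRAME_BASE",
    "FRAME_RSC",
    "FRAME_TRAJ",
    "FRAME_IMG",
    "RigidTransform",
    "compose",
    "invert",
    "random_rigid_transform",
]

FRAME_BASE = "BASE"
FRAME_RSC = "RSC"
FRAME_TRAJ = "TRAJ"
FRAME_IMG = "IMG"

#: rotations with ‖RᵀR − I‖_max at or below this are accepted verbatim
ORTHONORMAL_TOL = 1e-10
#: rotations off by up to this much (text round-off) are re-orthonormalized
REORTHONORMALIZE_TOL = 1e-6


def _clean_rotation(rotation: np.ndarray) -> np.ndarray:
    """Validate a 3x3 rotation, re-projecting mild round-off via polar decomposition."""
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValidationError(f"rotation must be 3x3, got {rotation.shape}")
    defect = np.abs(rotation.T @ rotation - np.eye(3)).max()
    if defect > REORTHONORMALIZE_TOL:
        raise ValidationError(
            f"rotation is not orthonormal (‖RᵀR − I‖_max = {defect:.3e} > "
            f"{REORTHONORMALIZE_TOL:g}); refusing to repair"
        )
    if defect > ORTHONORMAL_TOL:
        # nearest orthogonal matrix in Frobenius norm
        rotation, _ = polar(rotation)
    if np.linalg.det(rotation) < 0:
        raise ValidationError("rotation has det = -1 (reflection); proper rotations only")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform mapping ``from_frame`` coordinates into ``to_frame``.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with det +1. Matrices within ``1e-6`` of
        orthonormal (file round-off) are silently re-projected; anything
        worse is rejected.
    translation
        3-vector in mm.
    from_frame, to_frame
        Frame labels, checked on composition.
    """

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str = field(default="?")
    to_frame: str = field(default="?")

    def __post_init__(self):
        rot = _clean_rotation(self.rotation)
        trans = np.asarray(self.translation, dtype=float).reshape(3).copy()
        rot = rot.copy()
        rot.flags.writeable = False
        trans.flags.writeable = False
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls, frame: str = "?") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), from_frame=frame, to_frame=frame)

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, from_frame: str = "?", to_frame: str = "?"
    ) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValidationError(f"homogeneous matrix must be 4x4, got {matrix.shape}")
        if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValidationError("last row of a homogeneous transform must be [0,0,0,1]")
        return cls(matrix[:3, :3], matrix[:3, 3], from_frame=from_frame, to_frame=to_frame)

    @classmethod
    def from_rotvec(
        cls,
        rotvec_deg: np.ndarray,
        translation: np.ndarray = (0.0, 0.0, 0.0),
        from_frame: str = "?",
        to_frame: str = "?",
    ) -> "RigidTransform":
        """Axis-angle construction; the rotation vector is in degrees."""
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(rot.as_matrix(), translation, from_frame=from_frame, to_frame=to_frame)

    @classmethod
    def translation_only(
        cls, translation: np.ndarray, from_frame: str = "?", to_frame: str = "?"
    ) -> "RigidTransform":
        return cls(np.eye(3), translation, from_frame=from_frame, to_frame=to_frame)

    # -- algebra ------------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (shape (3,) or (N, 3), mm) from ``from_frame`` into ``to_frame``."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_direction(self, direction: np.ndarray) -> np.ndarray:
        """Rotate a free vector (no translation)."""
        return np.asarray(direction, dtype=float) @ self.rotation.T

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def relabel(self, from_frame: str | None = None, to_frame: str | None = None):
        return RigidTransform(
            self.rotation,
            self.translation,
            from_frame=self.from_frame if from_frame is None else from_frame,
            to_frame=self.to_frame if to_frame is None else to_frame,
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"RigidTransform({self.to_frame}<-{self.from_frame}, "
            f"t={np.array2string(self.translation, precision=3)})"
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Chain two transforms: the result maps ``b.from_frame`` into ``a.to_frame``.

    Frame labels must be compatible (``a.from_frame == b.to_frame``); the
    wildcard label ``"?"`` composes with anything.
    """
    if "?" not in (a.from_frame, b.to_frame) and a.from_frame != b.to_frame:
        raise FrameMismatchError(
            f"cannot compose {a.to_frame}<-{a.from_frame} with {b.to_frame}<-{b.from_frame}: "
            f"inner frames disagree ({a.from_frame!r} vs {b.to_frame!r})"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        from_frame=b.from_frame,
        to_frame=a.to_frame,
    )


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform; frame labels swap."""
    rot_inv = t.rotation.T
    return RigidTransform(
        rot_inv, -rot_inv @ t.translation, from_frame=t.to_frame, to_frame=t.from_frame
    )


def random_rigid_transform(
    rng: np.random.Generator,
    max_translation: float = 50.0,
    from_frame: str = "?",
    to_frame: str = "?",
) -> RigidTransform:
    """Uniform random rotation (Haar via random quaternion) + uniform translation."""
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(rot, trans, from_frame=from_frame, to_frame=to_frame)
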