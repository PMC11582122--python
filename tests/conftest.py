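import numpy as np
import pytest

from psaforge.frames import FRAME_IMG, FRAME_RSC, RigidTransform, random_rigid_transform
from psaforge.registration import FiducialSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_fiducials(frame: str = FRAME_RSC) -> FiducialSet:
    """Four well-separated non-coplanar markers."""
    centers = np.array(
        [[16.0, 0.0, 0.0], [-14.0, 10.0, 1.0], [-10.0, -14.0, 3.0], [4.0, 5.0, 12.0]]
    )
    return FiducialSet(("F1", "F2", "F3", "F4"), centers, frame)


def transform_fiducials(fid: FiducialSet, t: RigidTransform, frame: str) -> FiducialSet:
    return FiducialSet(fid.labels, t.apply(fid.centers), frame)


def rotation_angle_deg(r_a: np.ndarray, r_b: np.ndarray) -> float:
    """Geodesic angle between two rotation matrices, degrees."""
    rel = r_a.T @ r_b
    return float(np.degrees(np.arccos(np.clip((np.trace(rel) - 1.0) / 2.0, -1.0, 1.0))))
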