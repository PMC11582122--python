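"""Trajectory planning: marker localization and the trajectory frame.

Three planned points define the insertion:

* ``P1`` — center of the round window, the entry into the scala tympani;
* ``P2`` — a second point placed so that P1->P2 runs tangential to the basal
  turn and central in the scala tympani cross-section;
* ``P3`` — a point about three quarters around the first cochlear turn that
  fixes the curling direction, i.e. the rotational orientation of the
  electrode array toward the modiolus.

From these the trajectory coordinate system CS_TRAJ is built with origin P1,
z along P1->P2 and x toward P3's in-plane projection. The same module
localizes the spherical registration markers in a voxel volume (threshold ->
connected components -> size filter -> sphere fit) so that planning and
registration can run on image data alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateGeometryError,
    DetectionCountError,
    FrameMismatchError,
    IOFailureError,
    ValidationError,
)
from .frames import FRAME_RSC, FRAME_TRAJ, RigidTransform
from .registration import FiducialSet, RegistrationResult, canonical_fiducial_order

__all__ = [
    "PlanningPoints",
    "TrajectoryFrame",
    "VoxelVolume",
    "fit_sphere_centers",
    "build_trajectory_frame",
    "map_planning_to_rsc",
]

MIN_TRAJECTORY_LENGTH = 1.0  # mm, ‖P2 − P1‖ below this is ill-conditioned
MIN_P3_OFFSET = 0.5  # mm, perpendicular distance of P3 from the P1–P2 line


@dataclass(frozen=True)
class PlanningPoints:
    """The three planned points, in mm, in one labeled frame."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    frame: str

    def __post_init__(self):
        for name in ("p1", "p2", "p3"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3).copy()
            v.flags.writeable = False
            object.__setattr__(self, name, v)
        d = self.p2 - self.p1
        length = np.linalg.norm(d)
        if length < MIN_TRAJECTORY_LENGTH:
            raise DegenerateGeometryError(
                f"‖P2 − P1‖ = {length:.3f} mm < {MIN_TRAJECTORY_LENGTH} mm; "
                "trajectory direction ill-conditioned"
            )
        z = d / length
        lateral = (self.p3 - self.p1) - np.dot(self.p3 - self.p1, z) * z
        if np.linalg.norm(lateral) < MIN_P3_OFFSET:
            raise DegenerateGeometryError(
                f"P3 lies {np.linalg.norm(lateral):.3f} mm from the P1–P2 line "
                f"(< {MIN_P3_OFFSET} mm); curling direction undefined"
            )

    def as_array(self) -> np.ndarray:
        return np.stack([self.p1, self.p2, self.p3])


@dataclass(frozen=True)
class TrajectoryFrame:
    """CS_TRAJ expressed in its parent frame; origin is P1."""

    pose: RigidTransform  # parent <- TRAJ

    @property
    def origin(self) -> np.ndarray:
        return self.pose.translation

    @property
    def direction(self) -> np.ndarray:
        """Unit insertion direction (the frame's z-axis) in the parent frame."""
        return self.pose.rotation[:, 2].copy()


def build_trajectory_frame(pts: PlanningPoints) -> TrajectoryFrame:
    """Construct CS_TRAJ: origin P1, z = unit(P2−P1), x toward P3, y = z × x.

    The in-plane x-axis is the Gram–Schmidt residual of (P3 − P1) against z,
    so P3 fixes the roll about the insertion axis; the frame is right-handed
    by construction.
    """
    z = pts.p2 - pts.p1
    z = z / np.linalg.norm(z)
    x = (pts.p3 - pts.p1) - np.dot(pts.p3 - pts.p1, z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    rotation = np.column_stack([x, y, z])
    pose = RigidTransform(rotation, pts.p1, from_frame=FRAME_TRAJ, to_frame=pts.frame)
    return TrajectoryFrame(pose)


def map_planning_to_rsc(pts: PlanningPoints, reg: RegistrationResult) -> PlanningPoints:
    """Carry image-space planning points into the carrier frame via the registration."""
    t = reg.transform
    if t.from_frame != pts.frame:
        raise FrameMismatchError(
            f"registration maps {t.to_frame}<-{t.from_frame} but points are in {pts.frame}"
        )
    if t.to_frame != FRAME_RSC:
        raise FrameMismatchError(f"registration must target RSC, maps to {t.to_frame}")
    return PlanningPoints(
        t.apply(pts.p1), t.apply(pts.p2), t.apply(pts.p3), frame=t.to_frame
    )


# ---------------------------------------------------------------------------
# Voxel volumes and marker localization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelVolume:
    """Scalar intensity grid with physical geometry.

    ``data[i, j, k]`` sits at world position ``origin + spacing * (i, j, k)``
    (mm): voxel indices are 0-based and the origin is the *center* of voxel
    (0, 0, 0), matching the ITK convention so round-trips through NRRD are
    exact.
    """

    data: np.ndarray
    spacing: np.ndarray  # mm per voxel along each axis
    origin: np.ndarray  # mm, world position of voxel (0,0,0) center

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got {data.ndim}-D")
        spacing = np.asarray(self.spacing, dtype=float).reshape(3).copy()
        if np.any(spacing <= 0):
            raise ValidationError(f"spacing must be positive, got {spacing}")
        origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        for arr in (spacing, origin):
            arr.flags.writeable = False
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    # -- NRRD I/O (via SimpleITK) ------------------------------------------

    def write_nrrd(self, path) -> None:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T))
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        try:
            sitk.WriteImage(img, str(path))
        except RuntimeError as exc:  # pragma: no cover - disk failures
            raise IOFailureError(f"could not write {path}: {exc}") from exc

    @classmethod
    def read_nrrd(cls, path) -> "VoxelVolume":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise IOFailureError(f"could not read {path}: {exc}") from exc
        data = sitk.GetArrayFromImage(img).T  # sitk returns (z, y, x)
        return cls(np.asarray(data, dtype=float), img.GetSpacing(), img.GetOrigin())


def _fit_sphere_surface(points: np.ndarray):
    """Algebraic least-squares sphere through points: returns (center, radius).

    Linearizes ‖p − c‖² = r² into 2 c·p + (r² − ‖c‖²) = ‖p‖² and solves the
    resulting linear system; exact for noise-free data on a sphere.
    """
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def fit_sphere_centers(
    vol: VoxelVolume,
    expected_radius: float,
    expected_count: int,
    frame: str = "IMG",
    size_tolerance: float = 0.4,
    return_radii: bool = False,
):
    """Localize spherical markers in a volume at sub-voxel precision.

    Pipeline: Otsu threshold -> connected components -> reject components
    whose voxel count deviates more than ``size_tolerance`` (fraction) from
    the ideal sphere volume -> per component, algebraic sphere fit to the
    surface voxels for the radius, then an intensity-weighted centroid over a
    one-voxel dilation of the component for the center. The partial-volume
    intensities at the rim are what carry the sub-voxel information, so the
    weighted centroid is the precision step; the surface fit alone is
    quantized at the voxel size.

    Returns exactly ``expected_count`` centers as a :class:`FiducialSet`
    labeled F1..Fn in the canonical centroid-distance order.
    """
    if expected_radius <= 2.0 * vol.spacing.max():
        raise ValidationError(
            f"expected radius {expected_radius} mm must exceed twice the "
            f"largest voxel spacing ({vol.spacing.max()} mm)"
        )
    if expected_count < 1:
        raise ValidationError("expected_count must be >= 1")
    data = vol.data
    if data.max() <= data.min():
        raise DetectionCountError("volume is constant; no markers detectable")
    thresh = threshold_otsu(data)
    mask = data > thresh
    labels_img = measure.label(mask, connectivity=1)
    ideal_voxels = (4.0 / 3.0) * np.pi * expected_radius**3 / vol.voxel_volume_mm3
    candidates = []
    rejected = []
    for region in measure.regionprops(labels_img):
        dev = abs(region.num_pixels - ideal_voxels) / ideal_voxels
        if dev > size_tolerance:
            rejected.append((region.label, region.num_pixels))
            continue
        candidates.append(region)
    if len(candidates) != expected_count:
        raise DetectionCountError(
            f"found {len(candidates)} marker candidates, expected {expected_count} "
            f"(threshold {thresh:.3g}, ideal size {ideal_voxels:.0f} voxels, "
            f"rejected components: {rejected})"
        )

    centers = np.empty((expected_count, 3))
    radii = np.empty(expected_count)
    for i, region in enumerate(candidates):
        comp = labels_img == region.label
        # surface voxels: in the component but with at least one 6-neighbor outside
        eroded = comp.copy()
        eroded[1:-1, 1:-1, 1:-1] = (
            comp[1:-1, 1:-1, 1:-1]
            & comp[:-2, 1:-1, 1:-1] & comp[2:, 1:-1, 1:-1]
            & comp[1:-1, :-2, 1:-1] & comp[1:-1, 2:, 1:-1]
            & comp[1:-1, 1:-1, :-2] & comp[1:-1, 1:-1, 2:]
        )
        surface_idx = np.argwhere(comp & ~eroded)
        center0, radii[i] = _fit_sphere_surface(vol.index_to_world(surface_idx))
        # refine with partial-volume weights inside radius + 1.5 voxels
        reach = expected_radius + 1.5 * vol.spacing.max()
        lo = np.maximum(np.floor((center0 - vol.origin - reach) / vol.spacing), 0).astype(int)
        hi = np.minimum(
            np.ceil((center0 - vol.origin + reach) / vol.spacing).astype(int) + 1,
            data.shape,
        )
        sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        idx = np.stack(
            np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij"), -1
        )
        world = vol.origin + idx * vol.spacing
        w = np.clip(sub, 0.0, None)
        wsum = w.sum()
        if wsum <= 0:
            raise DetectionCountError("candidate component has no positive intensity")
        centers[i] = (w[..., None] * world).sum(axis=(0, 1, 2)) / wsum

    order = canonical_fiducial_order(centers)
    labels = tuple(f"F{i + 1}" for i in range(expected_count))
    result = FiducialSet(labels, centers[order], frame)
    if return_radii:
        return result, radii[order]
    return result
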