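"""JSON case files: the single input document of the CLI.

A case file aggregates everything the adapter computation needs: the
carrier's measured marker centers (carrier frame), the markers observed in
image space (either directly as points or as a voxel volume to localize
them in), the three planning points (image frame), the bench calibration
transform, optional build-spec overrides and metadata. All lengths are mm;
every transform carries explicit frame labels and is stored as a row-major
4x4 matrix.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydantic

from .errors import IOFailureError, ValidationError
from .frames import FRAME_BASE, FRAME_IMG, FRAME_RSC, FRAME_TRAJ, RigidTransform
from .geometry import PSABuildSpec
from .planning import PlanningPoints, VoxelVolume, fit_sphere_centers
from .registration import CalibrationModel, FiducialSet

__all__ = [
    "CaseFileModel",
    "LoadedCase",
    "load_case",
    "dump_case",
    "case_from_synthetic",
    "sha256_of_file",
]

Vec3 = tuple[float, float, float]


class TransformModel(pydantic.BaseModel):
    rows: tuple[tuple[float, float, float, float], ...] = pydantic.Field(
        min_length=4, max_length=4
    )
    from_frame: str
    to_frame: str

    def to_rigid(self) -> RigidTransform:
        return RigidTransform.from_matrix(
            np.asarray(self.rows, dtype=float), self.from_frame, self.to_frame
        )

    @classmethod
    def from_rigid(cls, t: RigidTransform) -> "TransformModel":
        return cls(
            rows=tuple(map(tuple, t.matrix.tolist())),
            from_frame=t.from_frame,
            to_frame=t.to_frame,
        )


class FiducialSetModel(pydantic.BaseModel):
    labels: tuple[str, ...]
    centers_mm: tuple[Vec3, ...]
    frame: str

    def to_set(self) -> FiducialSet:
        return FiducialSet(self.labels, np.asarray(self.centers_mm, dtype=float), self.frame)

    @classmethod
    def from_set(cls, s: FiducialSet) -> "FiducialSetModel":
        return cls(
            labels=s.labels, centers_mm=tuple(map(tuple, s.centers.tolist())), frame=s.frame
        )


class PlanningModel(pydantic.BaseModel):
    p1_mm: Vec3
    p2_mm: Vec3
    p3_mm: Vec3
    frame: str = FRAME_IMG

    def to_points(self) -> PlanningPoints:
        return PlanningPoints(self.p1_mm, self.p2_mm, self.p3_mm, self.frame)


class VolumeRefModel(pydantic.BaseModel):
    path: str  # NRRD, relative to the case file
    expected_sphere_radius_mm: float = 2.5
    expected_count: int = 4


class BuildSpecModel(pydantic.BaseModel):
    """Optional overrides of the adapter build parameters."""

    model_config = pydantic.ConfigDict(extra="forbid")

    fit_offset: float | None = None
    cloud_pitch: float | None = None
    alpha_radius: float | None = None
    connector_height: float | None = None
    base_size: tuple[float, float, float] | None = None
    chamfer_angle_deg: float | None = None
    chamfer_depth: float | None = None
    cylinder_radius: float | None = None
    max_tilt_deg: float | None = None
    max_lateral_offset: float | None = None

    def to_spec(self, base: PSABuildSpec | None = None) -> PSABuildSpec:
        return (base or PSABuildSpec()).with_overrides(
            **self.model_dump(exclude_none=True)
        )


class MetadataModel(pydantic.BaseModel):
    id: str = "case"
    side: str | None = None
    seed: int | None = None


class CaseFileModel(pydantic.BaseModel):
    """Schema of the on-disk JSON case file."""

    model_config = pydantic.ConfigDict(extra="forbid")

    format: str = "psaforge-case/1"
    metadata: MetadataModel = MetadataModel()
    fiducials_measured: FiducialSetModel
    fiducials_image: FiducialSetModel | None = None
    volume: VolumeRefModel | None = None
    planning_points: PlanningModel
    calibration: TransformModel
    build_spec: BuildSpecModel = BuildSpecModel()

    @pydantic.model_validator(mode="after")
    def _check_image_source(self):
        if self.fiducials_image is None and self.volume is None:
            raise ValueError("case must provide fiducials_image or a volume")
        return self


@dataclass(frozen=True)
class LoadedCase:
    """Validated, frame-checked domain objects ready for the pipeline."""

    case_id: str
    fiducials_rsc: FiducialSet
    fiducials_img: FiducialSet
    planning_img: PlanningPoints
    calibration: CalibrationModel
    spec: PSABuildSpec
    seed: int
    source_sha256: str | None = None


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_case(path, spec_overrides: dict | None = None) -> LoadedCase:
    """Read and validate a JSON case file into domain objects.

    If the image-side markers come as a volume reference, the spheres are
    localized with :func:`fit_sphere_centers` on load. ``spec_overrides``
    (e.g. CLI flags) take precedence over the case file's build block.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except OSError as exc:
        raise IOFailureError(f"could not read case file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ValidationError(f"case file {path} is not valid JSON: {exc}") from exc
    try:
        model = CaseFileModel.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"case file {path} failed schema validation:\n{exc}") from exc

    fiducials_rsc = model.fiducials_measured.to_set()
    if fiducials_rsc.frame != FRAME_RSC:
        raise ValidationError(
            f"measured fiducials must be in frame {FRAME_RSC}, got {fiducials_rsc.frame}"
        )
    if model.fiducials_image is not None:
        fiducials_img = model.fiducials_image.to_set()
    else:
        vol_path = path.parent / model.volume.path
        vol = VoxelVolume.read_nrrd(vol_path)
        fiducials_img = fit_sphere_centers(
            vol,
            model.volume.expected_sphere_radius_mm,
            model.volume.expected_count,
            frame=FRAME_IMG,
        )
    if fiducials_img.frame != FRAME_IMG:
        raise ValidationError(
            f"image fiducials must be in frame {FRAME_IMG}, got {fiducials_img.frame}"
        )
    calibration = CalibrationModel(model.calibration.to_rigid())
    spec = model.build_spec.to_spec()
    if spec_overrides:
        spec = spec.with_overrides(**spec_overrides)
    return LoadedCase(
        case_id=model.metadata.id,
        fiducials_rsc=fiducials_rsc,
        fiducials_img=fiducials_img,
        planning_img=model.planning_points.to_points(),
        calibration=calibration,
        spec=spec,
        seed=model.metadata.seed if model.metadata.seed is not None else 0,
        source_sha256=sha256_of_file(path),
    )


def case_from_synthetic(case) -> CaseFileModel:
    """Serialize a :class:`~psaforge.synthetic.SyntheticCase` as a case file."""
    return CaseFileModel(
        metadata=MetadataModel(id=case.case_id, side=case.side, seed=case.seed),
        fiducials_measured=FiducialSetModel.from_set(case.fiducials_rsc),
        fiducials_image=FiducialSetModel.from_set(case.fiducials_img),
        planning_points=PlanningModel(
            p1_mm=tuple(case.planning_img.p1),
            p2_mm=tuple(case.planning_img.p2),
            p3_mm=tuple(case.planning_img.p3),
            frame=case.planning_img.frame,
        ),
        calibration=TransformModel.from_rigid(case.calibration.base_to_traj),
    )


def dump_case(model: CaseFileModel, path) -> None:
    Path(path).write_text(model.model_dump_json(indent=2))
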