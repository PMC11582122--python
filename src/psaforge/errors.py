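"""Exception hierarchy with CLI exit codes.

Exit-code contract: 0 success, 2 validation, 3 geometry/feasibility, 4 I/O.
"""


class PsaForgeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(PsaForgeError):
    """Malformed or inconsistent input data."""

    exit_code = 2


class FrameMismatchError(ValidationError):
    """Transform composition or point mapping with incompatible frame labels."""


class InsufficientFiducialsError(ValidationError):
    """Fewer than three common fiducial labels between two sets."""


class GeometryError(PsaForgeError):
    """Geometric computation failed or is infeasible."""

    exit_code = 3


class DegenerateGeometryError(GeometryError):
    """Collinear fiducials, coincident planning points, and similar."""


class DetectionCountError(GeometryError):
    """Sphere detection found a different number of markers than expected."""


class WorkspaceInfeasibleError(GeometryError):
    """Requested adapter pose lies outside the buildable workspace."""


class CollisionError(GeometryError):
    """Adapter sub-models interpenetrate where they must not."""


class AlphaTooSmallError(GeometryError):
    """Alpha-shape of the union cloud fragments into multiple components."""

    def __init__(self, msg: str, suggested_alpha: float | None = None):
        super().__init__(msg)
        self.suggested_alpha = suggested_alpha


class MeshNotWatertightError(GeometryError):
    """Mesh violates the printability contract (open edges)."""


class IOFailureError(PsaForgeError):
    """File could not be read or written."""

    exit_code = 4
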