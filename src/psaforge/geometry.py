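"""Solid modeling of the pose setting adapter (PSA).

The adapter realizes the computed carrier pose ``base_T_rsc`` with two
functional surfaces: its bottom sits on the bench base (CS_BASE, z = 0) and
its top carries the brick interface that clamps the carrier's 2x2 plate, so
the interface plane and edge directions reproduce CS_RSC. Between them the
solid is assembled from three parametric sub-models sampled as point clouds:

* **connector** — block carrying the brick interface, posed at CS_RSC;
* **base** — chamfered cuboid resting on the bench, clamped there;
* **cylinder** — vertical pillar joining base top to connector, centered
  under the CS_RSC origin.

The union cloud is solidified with a 3-D alpha shape (Delaunay
tetrahedralization filtered by circumradius; the boundary of the surviving
alpha complex is the printable surface) and exported as STL.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.spatial import Delaunay

from .errors import (
    AlphaTooSmallError,
    CollisionError,
    MeshNotWatertightError,
    ValidationError,
    WorkspaceInfeasibleError,
)
from .frames import FRAME_BASE, FRAME_RSC, RigidTransform

__all__ = [
    "PSABuildSpec",
    "PSAGeometry",
    "FeasibilityReport",
    "generate_submodel_clouds",
    "alpha_shape",
    "solidify",
    "export_stl",
    "check_feasibility",
    "fit_interface_frame",
    "sample_feasible_poses",
]


@dataclass(frozen=True)
class PSABuildSpec:
    """Parametric dimensions of the adapter, all in mm / degrees.

    The brick interface uses the public nominal brick module (8 mm pitch; a
    2x2 plate spans 16 x 16 mm); ``fit_offset`` grows or shrinks the
    interface footprint for clearance/oversize fits and is limited to the
    ±0.1 mm range that consumer FDM printing resolves meaningfully — the
    exact fit (0.0) clamps best and is the default. Cloud pitch and alpha
    radius control the sampling of the sub-model clouds and the alpha-shape
    solidification; alpha defaults to twice the pitch, the smallest radius
    that reliably bridges a regular grid diagonal.
    """

    brick_module_pitch: float = 8.0
    brick_interface_footprint: tuple[float, float] = (16.0, 16.0)
    fit_offset: float = 0.0
    connector_height: float = 4.0
    base_size: tuple[float, float, float] = (24.0, 24.0, 6.0)  # L x W x H
    chamfer_angle_deg: float = 45.0
    chamfer_depth: float = 3.0
    cylinder_radius: float = 3.0
    cloud_pitch: float = 0.5
    alpha_radius: float | None = None  # None -> 2 * cloud_pitch
    max_tilt_deg: float = 40.0
    max_lateral_offset: float = 8.0
    max_connector_height: float = 40.0

    def __post_init__(self):
        if self.cloud_pitch <= 0:
            raise ValidationError("cloud_pitch must be positive")
        if self.alpha < self.cloud_pitch:
            raise ValidationError(
                f"alpha_radius {self.alpha} < cloud_pitch {self.cloud_pitch}: "
                "the alpha shape would fragment"
            )
        if not -0.1 <= self.fit_offset <= 0.1:
            raise ValidationError(
                f"fit_offset {self.fit_offset} mm outside the supported ±0.1 mm range"
            )
        if min(self.base_size) <= 0 or self.connector_height <= 0 or self.cylinder_radius <= 0:
            raise ValidationError("all dimensions must be positive")

    @property
    def alpha(self) -> float:
        return 2.0 * self.cloud_pitch if self.alpha_radius is None else self.alpha_radius

    def with_overrides(self, **kwargs) -> "PSABuildSpec":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass(frozen=True)
class PSAGeometry:
    """Sub-model point clouds (CS_BASE, mm) and, after solidification, the mesh."""

    connector_cloud: np.ndarray
    cylinder_cloud: np.ndarray
    base_cloud: np.ndarray
    pose: RigidTransform  # BASE <- RSC used to place the connector
    spec: PSABuildSpec
    mesh: trimesh.Trimesh | None = None

    @property
    def union_cloud(self) -> np.ndarray:
        return np.vstack([self.connector_cloud, self.cylinder_cloud, self.base_cloud])


@dataclass(frozen=True)
class FeasibilityReport:
    """Workspace check for a candidate adapter pose."""

    tilt_deg: float
    lateral_offset_mm: float
    connector_height_mm: float
    connector_clearance_mm: float  # lowest connector corner above the base top
    collision: bool
    tilt_ok: bool
    offset_ok: bool
    height_ok: bool
    feasible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def _grid1d(lo: float, hi: float, pitch: float) -> np.ndarray:
    """Boundary-inclusive sampling of [lo, hi]; endpoints are exact."""
    n = max(int(np.ceil((hi - lo) / pitch)), 1)
    return np.linspace(lo, hi, n + 1)


def _grid3d(bounds, pitch: float) -> np.ndarray:
    axes = [_grid1d(lo, hi, pitch) for lo, hi in bounds]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


def _connector_corners(pose: RigidTransform, spec: PSABuildSpec) -> np.ndarray:
    fx = spec.brick_interface_footprint[0] + spec.fit_offset
    fy = spec.brick_interface_footprint[1] + spec.fit_offset
    sx = np.array([-fx / 2, fx / 2])
    sz = np.array([-spec.connector_height, 0.0])
    corners = np.array(
        [[x, y, z] for x in sx for y in (-fy / 2, fy / 2) for z in sz]
    )
    return pose.apply(corners)


def check_feasibility(pose: RigidTransform, spec: PSABuildSpec) -> FeasibilityReport:
    """Report whether a carrier pose is buildable; never raises.

    Tilt is the angle between the carrier z-axis and the bench vertical;
    lateral offset is the in-plane distance of the CS_RSC origin from the
    bench axis; collision means a connector corner dips below the base top.
    """
    tilt = float(np.degrees(np.arccos(np.clip(pose.rotation[2, 2], -1.0, 1.0))))
    lateral = float(np.linalg.norm(pose.translation[:2]))
    height = float(pose.translation[2])
    base_top = spec.base_size[2]
    clearance = float(_connector_corners(pose, spec)[:, 2].min() - base_top)
    reasons = []
    tilt_ok = tilt <= spec.max_tilt_deg + 1e-9
    if not tilt_ok:
        reasons.append(f"tilt {tilt:.1f} deg exceeds limit {spec.max_tilt_deg} deg")
    offset_ok = lateral <= spec.max_lateral_offset + 1e-9
    if not offset_ok:
        reasons.append(
            f"lateral offset {lateral:.1f} mm exceeds limit {spec.max_lateral_offset} mm"
        )
    height_ok = height <= spec.max_connector_height + 1e-9
    if not height_ok:
        reasons.append(f"connector height {height:.1f} mm exceeds workspace")
    collision = clearance < 0.0
    if collision:
        reasons.append(
            f"connector corner dips {-clearance:.2f} mm below the base top plane"
        )
    feasible = tilt_ok and offset_ok and height_ok and not collision
    return FeasibilityReport(
        tilt, lateral, height, clearance, collision,
        tilt_ok, offset_ok, height_ok, feasible, tuple(reasons),
    )


def generate_submodel_clouds(pose: RigidTransform, spec: PSABuildSpec) -> PSAGeometry:
    """Sample the three sub-model solids as point clouds in CS_BASE.

    The connector block is a filled cuboid in carrier coordinates whose top
    face (the interface plane) is centered on the CS_RSC origin with edges
    along the carrier x/y axes, then rigidly posed. The base cuboid stands on
    the bench plane with a chamfer on its clamping edge. The cylinder is
    sampled vertically from just inside the base top up to 1 mm below the
    CS_RSC origin, so each neighboring pair of clouds overlaps by more than
    the alpha radius and the union solidifies into one component.
    """
    if pose.to_frame != FRAME_BASE or pose.from_frame != FRAME_RSC:
        raise ValidationError(
            f"pose must map RSC->BASE, got {pose.to_frame}<-{pose.from_frame}"
        )
    report = check_feasibility(pose, spec)
    if report.collision:
        raise CollisionError("; ".join(report.reasons))
    if not report.feasible:
        raise WorkspaceInfeasibleError("; ".join(report.reasons))
    pitch = spec.cloud_pitch

    fx = spec.brick_interface_footprint[0] + spec.fit_offset
    fy = spec.brick_interface_footprint[1] + spec.fit_offset
    connector_local = _grid3d(
        [(-fx / 2, fx / 2), (-fy / 2, fy / 2), (-spec.connector_height, 0.0)], pitch
    )
    connector = pose.apply(connector_local)

    length, width, height = spec.base_size
    base = _grid3d([(-length / 2, length / 2), (-width / 2, width / 2), (0.0, height)], pitch)
    # 45-degree-style chamfer on the +y top (clamping) edge: cut by the plane
    # through (y = W/2 - w_c, z = H) and (y = W/2, z = H - d)
    d = spec.chamfer_depth
    if d > 0:
        w_c = d / np.tan(np.radians(spec.chamfer_angle_deg))
        keep = d * (base[:, 1] - (width / 2 - w_c)) + w_c * (base[:, 2] - (height - d)) <= d * w_c + 1e-12
        base = base[keep]

    cx, cy, cz = pose.translation
    r = spec.cylinder_radius
    z_top = cz - 1.0
    z_bot = height - spec.alpha
    cyl = _grid3d([(cx - r, cx + r), (cy - r, cy + r), (z_bot, z_top)], pitch)
    cyl = cyl[(cyl[:, 0] - cx) ** 2 + (cyl[:, 1] - cy) ** 2 <= r**2 + 1e-12]

    return PSAGeometry(connector, cyl, base, pose, spec)


# ---------------------------------------------------------------------------
# Alpha shape
# ---------------------------------------------------------------------------


def _tetra_circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (vectorized); inf for degenerate tets."""
    a = points[tets[:, 0]]
    rows = np.stack([points[tets[:, k]] - a for k in (1, 2, 3)], axis=1)  # (T,3,3)
    rhs = 0.5 * np.einsum("tij,tij->ti", rows, rows)
    det = np.linalg.det(rows)
    ok = np.abs(det) > 1e-12
    radii = np.full(len(tets), np.inf)
    if ok.any():
        centers = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def _boundary_faces(kept: np.ndarray) -> np.ndarray:
    """Triangles owned by exactly one tetrahedron of the kept set."""
    faces = kept[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
    faces_sorted = np.sort(faces, axis=1)
    _, index, counts = np.unique(
        faces_sorted, axis=0, return_index=True, return_counts=True
    )
    return faces[index[counts == 1]]


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def _manifold_boundary(
    points: np.ndarray, kept: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary of the kept-tet union as an edge-manifold surface.

    The raw boundary can pinch: two solid regions touching only along an
    edge leave that edge shared by four (or more) boundary faces. Geometry
    and enclosed volume are correct; only the topology is non-manifold. The
    standard remedy is applied: the incident faces are grouped into wedges
    (fans connected through kept tetrahedra around the pinched edge) and the
    pinch vertices are duplicated per wedge, so each copy of the edge is used
    by exactly two faces. Returns (vertices, faces); vertices may contain
    duplicated coordinates, which downstream processing must not re-merge.
    """
    vertices = points
    boundary = _boundary_faces(kept)
    edges = np.sort(boundary[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bad_edges = uniq[counts != 2]
    if len(bad_edges) == 0:
        return vertices, boundary

    # wedge decomposition around each pinched edge: two faces containing the
    # edge belong together iff linked through kept tets incident to the edge
    wedge_of_face: dict[tuple, dict] = {}
    for a, b in bad_edges:
        incident = kept[((kept == a) | (kept == b)).sum(axis=1) == 2]
        uf = _UnionFind()
        for tet in incident:
            other = [v for v in tet if v != a and v != b]
            f1 = tuple(sorted((a, b, other[0])))
            f2 = tuple(sorted((a, b, other[1])))
            uf.union(f1, f2)
        groups = {}
        face_ids = np.flatnonzero(((boundary == a) | (boundary == b)).sum(axis=1) == 2)
        for fid in face_ids:
            key = tuple(sorted(boundary[fid]))
            groups.setdefault(uf.find(key), []).append(fid)
        wedge_of_face[(int(a), int(b))] = groups

    # split each pinch vertex: group its incident boundary faces into fans,
    # joined across manifold edges always and across pinched edges only
    # within a wedge; every fan beyond the first gets a duplicate vertex
    bad_edge_set = {(int(a), int(b)) for a, b in bad_edges}
    pinch_vertices = sorted({v for e in bad_edges for v in e})
    new_faces = boundary.copy()
    extra_coords = []
    next_id = len(vertices)
    for v in pinch_vertices:
        face_ids = np.flatnonzero((boundary == v).any(axis=1))
        uf = _UnionFind()
        by_edge: dict[tuple, list] = {}
        for fid in face_ids:
            uf.find(int(fid))
            for w in boundary[fid]:
                if w == v:
                    continue
                by_edge.setdefault((min(v, int(w)), max(v, int(w))), []).append(int(fid))
        for edge, fids in by_edge.items():
            if edge in bad_edge_set:
                for group in wedge_of_face[edge].values():
                    pair = [f for f in group if f in fids]
                    for f in pair[1:]:
                        uf.union(pair[0], f)
            else:
                for f in fids[1:]:
                    uf.union(fids[0], f)
        fans: dict = {}
        for fid in face_ids:
            fans.setdefault(uf.find(int(fid)), []).append(int(fid))
        for fan in list(fans.values())[1:]:
            extra_coords.append(vertices[v])
            for fid in fan:
                new_faces[fid][new_faces[fid] == v] = next_id
            next_id += 1
    if extra_coords:
        vertices = np.vstack([vertices, np.asarray(extra_coords)])

    edges = np.sort(new_faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if (counts != 2).any():
        raise MeshNotWatertightError(
            f"{int((counts != 2).sum())} non-manifold edges remain after pinch "
            "splitting; increase alpha or refine the cloud"
        )
    return vertices, new_faces


def alpha_shape(points: np.ndarray, alpha: float) -> trimesh.Trimesh:
    """Boundary mesh of the 3-D alpha complex of a point cloud.

    Tetrahedralizes the cloud (Delaunay), keeps tetrahedra whose circumradius
    is at most ``alpha`` and returns the triangles owned by exactly one kept
    tetrahedron — the watertight boundary of the alpha complex. A tiny
    deterministic jitter (1e-3 x alpha) breaks the cospherical degeneracies
    of regular grids; it is orders of magnitude below the cloud pitch.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValidationError("need at least 4 points for a solid alpha shape")
    rng = np.random.default_rng(160214)  # fixed: same cloud -> same mesh
    jittered = points + rng.normal(0.0, 1e-3 * alpha, points.shape)
    tri = Delaunay(jittered)
    radii = _tetra_circumradii(jittered, tri.simplices)
    keep = radii <= alpha
    if not keep.any():
        raise AlphaTooSmallError(
            f"no tetrahedron has circumradius <= alpha = {alpha}; cloud too sparse",
            suggested_alpha=2.0 * alpha,
        )
    vertices, boundary = _manifold_boundary(jittered, tri.simplices[keep])
    # process=False: pinch splitting relies on duplicated vertices staying split
    mesh = trimesh.Trimesh(vertices=vertices, faces=boundary, process=False)
    mesh.remove_unreferenced_vertices()
    bodies = mesh.body_count
    if bodies != 1:
        raise AlphaTooSmallError(
            f"alpha shape fragments into {bodies} components at alpha = {alpha}",
            suggested_alpha=1.5 * alpha,
        )
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def solidify(geometry: PSAGeometry, alpha_radius: float | None = None) -> PSAGeometry:
    """Alpha-shape the union cloud into a printable solid; returns geometry + mesh."""
    alpha = geometry.spec.alpha if alpha_radius is None else alpha_radius
    mesh = alpha_shape(geometry.union_cloud, alpha)
    if not mesh.is_watertight:
        raise MeshNotWatertightError(
            "alpha-shape boundary is not watertight; increase alpha or refine the cloud"
        )
    return replace(geometry, mesh=mesh)


# ---------------------------------------------------------------------------
# STL export
# ---------------------------------------------------------------------------


def export_stl(mesh: trimesh.Trimesh, path, format: str = "binary") -> None:
    """Write an STL file (mm units), refusing non-printable meshes.

    Binary STL is the default dialect; files are 84 + 50*T bytes for T
    triangles. The 80-byte header is fixed, so identical meshes produce
    byte-identical files.
    """
    if format not in ("binary", "ascii"):
        raise ValidationError(f"unknown STL format {format!r}")
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        raise MeshNotWatertightError(
            f"refusing to export a non-watertight mesh ({int((counts != 2).sum())} "
            "defective edges); not printable"
        )
    if format == "binary":
        tri = mesh.triangles.astype("<f4")
        normals = mesh.face_normals.astype("<f4")
        with open(path, "wb") as fh:
            fh.write(b"psaforge binary STL".ljust(80, b"\x00"))
            fh.write(struct.pack("<I", len(tri)))
            record = np.zeros(
                len(tri),
                dtype=np.dtype(
                    [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
                ),
            )
            record["normal"] = normals
            record["v"] = tri
            fh.write(record.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid psaforge\n")
            for normal, tri in zip(mesh.face_normals, mesh.triangles):
                fh.write(f"  facet normal {normal[0]:.6e} {normal[1]:.6e} {normal[2]:.6e}\n")
                fh.write("    outer loop\n")
                for v in tri:
                    fh.write(f"      vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid psaforge\n")


# ---------------------------------------------------------------------------
# Interface recovery (pose fidelity through meshing)
# ---------------------------------------------------------------------------


def fit_interface_frame(
    mesh: trimesh.Trimesh, nominal_pose: RigidTransform, spec: PSABuildSpec
) -> RigidTransform:
    """Re-estimate CS_RSC from the meshed connector interface.

    Selects mesh facets lying on the interface plane (near the nominal plane,
    with matching normal), fits the plane to them (area-weighted), takes the
    area-weighted facet centroid as the origin, and recovers the in-plane
    edge directions from the rim edges of the facet patch (folded modulo 90
    degrees, since the interface is square). The result is the as-meshed
    CS_RSC pose; comparing it against ``nominal_pose`` measures how
    faithfully meshing preserved the functional surface.
    """
    n_nom = nominal_pose.rotation[:, 2]
    origin_nom = nominal_pose.translation
    centroids = mesh.triangles_center
    normals = mesh.face_normals
    areas = mesh.area_faces
    plane_dist = (centroids - origin_nom) @ n_nom
    sel = (np.abs(plane_dist) < 0.35 * spec.cloud_pitch + 1e-6) & (normals @ n_nom > np.cos(np.radians(10)))
    if sel.sum() < 3:
        raise ValidationError("could not locate the connector interface facets")
    w = areas[sel]
    pts = centroids[sel]
    origin = (w[:, None] * pts).sum(axis=0) / w.sum()
    cov = ((pts - origin) * w[:, None]).T @ (pts - origin)
    _, vecs = np.linalg.eigh(cov)
    normal = vecs[:, 0]
    if normal @ n_nom < 0:
        normal = -normal

    # rim edges of the facet patch -> in-plane edge orientation modulo 90 deg:
    # an edge used by exactly one patch face lies on the patch boundary
    patch_faces = mesh.faces[sel]
    patch_edges = np.sort(
        patch_faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1
    )
    uniq, counts = np.unique(patch_edges, axis=0, return_counts=True)
    rim = uniq[counts == 1]
    if len(rim) < 4:
        raise ValidationError("interface rim not found")
    vec = mesh.vertices[rim[:, 1]] - mesh.vertices[rim[:, 0]]
    vec = vec - np.outer(vec @ normal, normal)
    length = np.linalg.norm(vec, axis=1)
    good = length > 1e-9
    vec, length = vec[good], length[good]
    x_ref = nominal_pose.rotation[:, 0]
    y_ref = np.cross(normal, x_ref)
    y_ref /= np.linalg.norm(y_ref)
    x_ref = np.cross(y_ref, normal)
    ang = np.arctan2(vec @ y_ref, vec @ x_ref)
    # fold to period pi/2 and average on the circle, weighted by edge length
    phase = np.exp(4j * ang)
    mean_angle = np.angle((length * phase).sum()) / 4.0
    x_axis = np.cos(mean_angle) * x_ref + np.sin(mean_angle) * y_ref
    y_axis = np.cross(normal, x_axis)
    rotation = np.column_stack([x_axis, y_axis, normal])
    return RigidTransform(rotation, origin, from_frame=FRAME_RSC, to_frame=FRAME_BASE)


def sample_feasible_poses(
    n: int,
    rng: np.random.Generator,
    spec: PSABuildSpec | None = None,
    tilt_range: tuple[float, float] = (0.0, 40.0),
) -> list[RigidTransform]:
    """Random feasible carrier poses spanning the given tilt range.

    Tilt is sampled uniformly over ``tilt_range`` about a uniform horizontal
    axis, with a uniform roll about the carrier axis, lateral offsets within
    the workspace and connector heights that clear the base.
    """
    spec = spec or PSABuildSpec()
    poses = []
    while len(poses) < n:
        tilt = rng.uniform(*tilt_range)
        azimuth = rng.uniform(0, 360)
        roll = rng.uniform(0, 360)
        axis = np.array([np.cos(np.radians(azimuth)), np.sin(np.radians(azimuth)), 0.0])
        t_tilt = RigidTransform.from_rotvec(axis * tilt)
        t_roll = RigidTransform.from_rotvec([0.0, 0.0, roll])
        rotation = (t_tilt.rotation @ t_roll.rotation)
        lateral = rng.uniform(-spec.max_lateral_offset, spec.max_lateral_offset, 2) / np.sqrt(2)
        height = rng.uniform(18.0, 26.0)
        pose = RigidTransform(
            rotation, [lateral[0], lateral[1], height],
            from_frame=FRAME_RSC, to_frame=FRAME_BASE,
        )
        if check_feasibility(pose, spec).feasible:
            poses.append(pose)
    return poses
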