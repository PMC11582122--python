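# Methods

## Problem and model

An insertion test bench measures the forces that arise while a cochlear
implant electrode array is advanced into a cochlear specimen. The measurement
is only meaningful if the planned insertion trajectory — chosen in a CT of
the specimen — is coaxial with the bench's insertion axis. `psaforge`
computes, and turns into a printable solid, the *pose setting adapter* (PSA)
that realizes this alignment for each individual specimen.

Four coordinate systems are involved: `BASE` (bench base, force-sensor
side), `RSC` (the reusable registration and specimen carrier holding the
specimen and four 5 mm spherical fiducials), `TRAJ` (the planned trajectory)
and `IMG` (CT space). Writing `A_T_B` for the rigid transform that maps
B-coordinates into A-coordinates, the adapter pose is

    BASE_T_RSC = BASE_T_TRAJ · (RSC_T_TRAJ)⁻¹

`BASE_T_TRAJ` is the bench **calibration matrix**: the pose at which the
trajectory must sit so that it lies on the common axis of the force sensor
and the insertion tool. Because it is measured rather than assumed ideal,
any manufacturing deviation of the bench is absorbed into the adapter.
`RSC_T_TRAJ` comes from the imaging chain: a point-based registration of the
fiducials (known exactly in `RSC`, localized in `IMG`) maps the planning
points into carrier coordinates, where the trajectory frame is constructed.
In exact arithmetic the chain closes identically — mounting the carrier at
`BASE_T_RSC` puts the planned trajectory exactly on the calibrated axis.
This closed loop is the package's central invariant and is asserted to
1e-9 (degrees / mm) over 100 random synthetic specimens.

## Registration and FRE

`register_fiducials` solves the least-squares rigid Procrustes problem with
the SVD (Kabsch) construction, including the determinant sign correction
that forbids reflections even for noisy, nearly planar marker layouts.
Correspondence is by label; unlabeled detections are ordered by a
rigid-invariant key (distance from the marker centroid, ties broken
lexicographically). The fiducial registration error is reported as the RMS
of the per-fiducial residuals — the dominant convention in the image-guidance
literature; per-fiducial residuals are exposed so a mean-of-distances summary
can be derived if needed. Registration statistics are validated against the
closed-form expectation for point-based registration,
`<FRE²> = (1 − 2/N)·<FLE²>`, by Monte-Carlo simulation (10 000 trials,
agreement within 5%).

## Trajectory frame

Three planned points define the insertion: P1 at the round-window center
(entry into the scala tympani), P2 placed so P1→P2 runs tangential to the
basal turn and central in the scala tympani, P3 about three quarters around
the first turn, fixing the roll of the frame about the insertion axis
(the orientation of the electrode toward the modiolus). The frame is
origin = P1, z = unit(P2−P1), x = Gram–Schmidt residual of (P3−P1) against
z, y = z × x. This in-plane convention is declared, not uniquely implied by
the three points' roles; any fixed convention yields the same insertion
axis. Guards: ‖P2−P1‖ ≥ 1 mm and P3 at least 0.5 mm off the P1–P2 line.

## Marker localization in volumes

Spheres are localized in CT-like volumes (default 0.3 mm isotropic voxels)
by: Otsu threshold → connected components → size filter (components whose
voxel count deviates more than 40% from the ideal sphere volume are
rejected) → algebraic least-squares sphere fit to each component's surface
voxels (Coope linearization; provides the radius) → intensity-weighted
centroid over a one-voxel dilation of the component. The last step is the
precision step: the partial-volume intensities at the sphere rim carry the
sub-voxel information, while the surface fit alone is quantized at the voxel
size. On noise-free synthetic renderings the center error is ~0.0005 mm at
0.3 mm voxels; the package asserts ≤ 0.1 mm over 200 off-grid placements,
with a mean ≤ 0.03 mm. Voxel convention: indices are 0-based, the volume
origin is the center of voxel (0,0,0), all coordinates physical mm
(matches ITK, so NRRD round-trips exactly).

## Adapter solid

The adapter is assembled from three parametric sub-models sampled as filled,
boundary-inclusive lattice clouds (pitch `cloud_pitch`) and solidified
together:

* **connector** — block carrying the 2×2 brick interface, posed so its top
  face centroid is the `RSC` origin and its edges follow the carrier x/y
  axes; footprint 16 × 16 mm (public nominal brick module, 8 mm pitch)
  plus `fit_offset` (±0.1 mm supported range; exact fit is the default as
  the best-clamping variant);
* **base** — cuboid standing on the bench plane (default 24 × 24 × 6 mm)
  with a 45°, 3 mm chamfer on the clamping edge;
* **cylinder** — vertical pillar (default radius 3 mm) from just inside the
  base top to 1 mm below the `RSC` origin, centered under that origin's
  vertical projection. Neighboring clouds overlap by more than the alpha
  radius so the union solidifies into one component.

Solidification is a 3-D alpha shape: Delaunay tetrahedralization of the
union cloud, keep tetrahedra with circumradius ≤ `alpha_radius` (default
2 × pitch, the smallest radius that reliably bridges a lattice diagonal),
boundary = triangles owned by exactly one kept tetrahedron. Two numerical
details matter:

* a deterministic jitter of 1e-3 × alpha (fixed seed, hence bit-identical
  meshes across runs) breaks the cospherical degeneracies of regular
  lattices before tetrahedralization;
* where two solid regions touch only along an edge the raw boundary is
  *pinched* (edge shared by four faces). The geometry is correct; only the
  topology is non-manifold. The boundary is manifoldized by wedge
  decomposition: faces around a pinched edge are grouped into fans connected
  through kept tetrahedra, and the pinch vertices are duplicated per fan.
  No material is added or removed.

The mesh must be watertight (every edge in exactly two faces), a single
body, positively oriented and of positive volume before STL export; export
refuses anything else (printability contract). Binary STL (84 + 50·T bytes,
fixed header) is the default; ASCII is available. Units are mm throughout.

Pose fidelity through meshing is verified by re-estimating the carrier frame
from the finished mesh: interface facets are selected near the nominal
plane, the plane is re-fit area-weighted, and the in-plane edge orientation
is recovered from the rim edges folded modulo 90° (the interface is square).
Over 50 random feasible poses spanning 0–40° tilt the recovered frame
agrees with the commanded pose within 0.5° and 1.5 × pitch.

`cloud_pitch` defaults to 0.5 mm. At that pitch a full adapter cloud is
~40 000 points and solidifies in a few seconds, the meshing error stays an
order of magnitude below the interface tolerances above, and the lattice
still resolves every parametric dimension exactly because the grids are
boundary-inclusive (footprints and heights are sampled at their exact
extents regardless of pitch). Halving the pitch roughly octuples the
tetrahedralization cost and is only worth it if sub-0.1 mm surface detail
is ever added to the sub-models.

### Workspace feasibility

A pose is buildable iff its tilt (angle between carrier z and bench
vertical) is within `max_tilt` (default 40°, the validated interface range),
its lateral offset within `max_lateral_offset` (default 8 mm, keeping the
pillar on the base), its height within the bench workspace, and no connector
corner dips below the base top plane (collision). `check_feasibility` always
returns a report; cloud generation raises on infeasible poses.

## Accuracy metrics

* **Angular deviation**: angle between the oriented planned and achieved
  insertion axis directions, degrees in [0, 180] (no folding at 90° —
  insertion axes are oriented).
* **Round-window offset**: both axes are intersected with the plane through
  the planned entry point normal to the planned direction; the in-plane
  distance of the intersection points is reported. "At the level of the
  round window" is deliberately operationalized as this in-plane distance,
  not the minimal 3-D line-to-line distance; the convention is declared so
  results are comparable.

`evaluate_case` carries the true trajectory through the (optionally
perturbed) mounting into the bench frame and scores it against the
calibration. Both metrics are invariant under a common rigid re-expression
of the bench frame, and a pure rotation about the entry point produces
angular error with exactly zero offset.

## Synthetic data

The generator emulates what dissection, CT scanning and bench calibration
would provide. The cochlea model is a planar logarithmic spiral
(decay 0.12 rad⁻¹) scaled so its footprint matches the basal-turn length
and width measures A × B, lifted helically at 1 mm per turn. Porcine
defaults: A = 7.31 mm, B = 5.30 mm, 3.5 turns (humans: A ≈ 8.4–9.2 mm,
B ≈ 6.2–7.0 mm, 2.5 turns). P1 sits at the basal opening, P2 3 mm along the
starting tangent, P3 three quarters around the first turn; the left side is
the exact mirror image of the right. Only this envelope is anatomical —
no scala-tympani cross-section, no modiolus, no insertion mechanics.

The specimen is posed on the carrier with a seeded tilt (default 0–35°,
leaving margin inside the 40° interface limit), spin and position; poses
whose computed adapter falls outside the workspace are redrawn, as an
experimenter would re-glue an awkward specimen. The default carrier layout
spans > 20 mm, is non-coplanar by > 2 mm with pairwise spacing > 10 mm and
distinct centroid distances (unambiguous canonical ordering). The bench
calibration is the ideal head-down target pose (entry point 32 mm above the
base, axis pointing down) composed with a small seeded deviation
(σ = 0.2° / 0.1 mm) — the imperfection the calibration matrix exists to
compensate, and the closed loop must absorb exactly.

Marker volumes are rendered with partial-volume weighting (5³ midpoint
subsamples per voxel), reproducing the rim intensities a reconstruction
shows; total intensity matches the analytic sphere volume within 1%.

Measurement noise is configurable and zero-mean Gaussian throughout:
fiducial localization σ per coordinate (default 0.05 mm, sub-voxel), print
pose error (default 0.2° / 0.1 mm per axis) and seating error (default 0).
These magnitudes are plausible for consumer FDM printing but are declared
stand-ins — the physical error distribution of a real bench is not asserted.
Consequently the Monte-Carlo study reproduces the *metric definitions* and
the zero-noise closed loop, and shows that plausible noise magnitudes land
in the few-tenths-of-mm / few-tenths-of-degree regime; it does not claim to
reproduce any measured per-specimen value.

## Determinism

Every stochastic component takes an explicit seed; the alpha-shape jitter
seed is fixed. Identical seeds give bit-identical case files, meshes, STL
bytes and CSV reports. Output files embed the tool version, the SHA-256 of
their input and the seed; no timestamps are written.

## Problem sizes used in the shipped checks

100 synthetic specimens for the closed loop; 100 random transforms for
registration recovery; 10 000 Monte-Carlo trials for the FRE² expectation;
200 off-grid sphere placements (50 volumes × 4); 50 meshed adapters spanning
0–40° tilt; 300 trials for the default-noise simulation summary.

## Known limitations

* The alpha shape under-fills curved surfaces by O(pitch) — the boundary
  interpolates lattice points strictly inside the true surface; volumes of
  strongly curved solids converge slowly in pitch (≈ −4% for a 5 mm
  hemisphere at 0.25 mm pitch).
* Pinch manifoldization leaves zero-thickness contacts in the exported
  surface where sub-models graze; slicers treat these as touching solids.
* The brick interface is modeled as its outer footprint only; stud/cavity
  geometry is not generated.
* Planning-point picking error is not modeled (only fiducial, print and
  seating noise); P2 is an input, not derived from a lumen centerline.
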