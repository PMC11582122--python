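# psaforge

Individualized **pose setting adapters** (PSAs) for cochlear-implant
insertion test benches.

Insertion-force measurements on cochlear specimens are only comparable if
the electrode array enters along the trajectory that was planned in the
specimen's CT — tangential to the basal turn, central in the scala tympani.
`psaforge` computes, for each specimen, the rigid pose a 3D-printed adapter
must realize between the bench base and the specimen carrier so that the
planned trajectory lies coaxially on the bench's insertion axis, and turns
that pose into a ready-to-print STL. It is aimed at labs running automated
insertion experiments who want alignment by geometry instead of manual
fine-tuning.

## The computation

With `A_T_B` the homogeneous transform mapping B-coordinates into
A-coordinates, and frames `BASE` (bench), `RSC` (registration and specimen
carrier), `TRAJ` (planned trajectory), `IMG` (CT):

1. **Registration** — the carrier's four 5 mm spherical fiducials, known
   exactly in `RSC` and localized in the CT (directly or by sub-voxel sphere
   fitting in the volume), give `RSC_T_IMG` by SVD least squares (Kabsch,
   reflection-free), with the fiducial registration error (FRE, RMS) as
   quality measure.
2. **Trajectory frame** — the three planning points (P1 round-window
   center, P2 fixing the insertion direction, P3 fixing the roll toward the
   modiolus) are mapped into `RSC` and define `RSC_T_TRAJ`
   (origin P1, z along P1→P2, x toward P3).
3. **Adapter pose** — with the measured bench calibration `BASE_T_TRAJ`:

       BASE_T_RSC = BASE_T_TRAJ · (RSC_T_TRAJ)⁻¹

   Because the calibration is measured, bench imperfections are compensated
   by the adapter itself; with exact inputs the planned trajectory lands
   exactly on the insertion axis (closed loop, asserted to 1e-9).
4. **Solid modeling** — connector block (brick interface at the carrier
   pose), chamfered base cuboid and connecting pillar are sampled as point
   clouds and solidified with a 3-D alpha shape into a watertight,
   single-body STL.

A synthetic-fixture module generates every input the physical workflow
would provide (porcine spiral-cochlea planning points with A = 7.31 mm,
B = 5.30 mm, 3.5 turns; carrier fiducial layouts; CT-like marker volumes at
0.3 mm voxels; seeded noise), so the whole chain runs and is tested without
any scan data. See `docs/methods.md` for the full model description.

## Worked example

Generate a synthetic case and build its adapter:

```python
from psaforge.synthetic import make_case
from psaforge.casefile import case_from_synthetic, dump_case

dump_case(case_from_synthetic(make_case(seed=3)), "case.json")
```

```text
$ psaforge build case.json -o out/
synthetic-00003: FRE 0.0000 mm, tilt 17.36 deg, 19600 triangles -> out/synthetic-00003.stl
```

The specimen's trajectory requires a 17.36° carrier tilt; the registration
residual is zero because the observations are noise-free, and
`out/synthetic-00003.pose.json` records the 4×4 pose, per-fiducial
residuals, feasibility report and the predicted accuracy of a perfect mount
(angular deviation 0.0°, round-window offset 0.0 mm — the closed loop).

Score the same case under an as-seated mounting error of 0.5° about the
carrier x-axis:

```text
$ psaforge verify case.json --perturb perturb.json
case,FRE [mm],Euclidean distance [mm],Angular deviation [deg]
synthetic-00003,0.0000,0.1049,0.4850
```

The tilt shows up as 0.485° of axis error (the axis is not perpendicular to
the perturbation axis, so slightly under 0.5°) and 0.105 mm of offset at the
round-window level, in the same columns a bench evaluation table uses.

Propagate the default measurement-noise model (fiducial localization
σ = 0.05 mm, print pose σ = 0.2° / 0.1 mm) through the whole pipeline:

```text
$ psaforge simulate conf.json -n 20 --seed 1
20 trials: angular 0.21 ± 0.10 deg, offset 0.13 ± 0.06 mm -> sim/trials.csv
```

i.e. with plausible consumer-FDM noise magnitudes the virtual bench aligns
specimens to a couple of tenths of a degree and of a millimeter.

## Layout

| module | contents |
| --- | --- |
| `psaforge.frames` | labeled rigid transforms, composition, inversion |
| `psaforge.registration` | fiducial sets, Kabsch fit, FRE, adapter pose |
| `psaforge.planning` | planning points, trajectory frame, sphere localization, NRRD |
| `psaforge.geometry` | build spec, sub-model clouds, alpha shape, STL, feasibility |
| `psaforge.metrics` | angular deviation, round-window offset, Monte-Carlo driver |
| `psaforge.synthetic` | spiral cochlea, carrier layouts, volume rendering, noise |
| `psaforge.casefile` / `psaforge.cli` | JSON case files; `build`, `verify`, `simulate` |
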