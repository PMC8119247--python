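# Methods

## The procedure

`pmct-overview` compresses a thorax/abdomen postmortem CT (PMCT) volume
into one 2D color-coded overview per view, in four steps:

1. **Load.** The volume is read from a DICOM series or NIfTI file and
   reoriented onto fixed canonical axes (x: subject-left→right,
   y: anterior→posterior, z: inferior→superior). Stored values are
   converted to Hounsfield units (HU) via the modality rescale and kept
   signed and unclamped — metal routinely exceeds the 12-bit range and
   the red rule needs values above 2800 HU.
2. **Segment exterior air.** Region growing from the eight volume
   corners (always outside the body) absorbs every voxel with
   HU ≤ −200 connected to them: surrounding air, body bags, and — via
   additional seeds detected inside the hollow CT table — the table's
   air-filled cavity, which the corners cannot reach. Gas enclosed by
   the body wall is untouched.
3. **Project.** For each view (anterior-posterior collapses y; lateral
   collapses x; images are head-up), three orthographic projections are
   computed: the MIP (ray maximum — bones, metal), the *selective*
   minIP (ray minimum over voxels **not** flagged in step 2 — only
   intracorporeal gas), and the average (ray mean — a radiograph-like
   soft-tissue reference).
4. **Composite.** Per pixel, in order:
   1. gray level = window(0.7·MIP + 0.3·AVG), window center 500 HU,
      width 1000 HU;
   2. MIP > 2800 HU → pure red (radiopaque material);
   3. minIP < −220 HU → pure blue (intracorporeal gas).

   Rules apply sequentially, so blue overwrites red where both fire.
   The result is exported as 8-bit RGB PNG; every pixel is gray
   (r = g = b), (255, 0, 0) or (0, 0, 255) by construction.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `air_threshold_hu` | −200 | HU | region-growing acceptance, **inclusive** (≤) |
| `red_threshold_hu` | 2800 | HU | red rule, **strict** (>) |
| `blue_threshold_hu` | −220 | HU | blue rule, **strict** (<) |
| `mip_weight` / `avg_weight` | 0.7 / 0.3 | — | gray blend; must sum to 1 |
| `window_center_hu` / `window_width_hu` | 500 / 1000 | HU | display window of the blended value |
| `connectivity` | `face` | — | 6-neighbourhood; `face+edge+corner` gives 26 |
| `table_seeds_enabled` | true | — | hollow-table cavity seeding |
| `table_shell_max_mm` | 10 | mm | max thickness of a run accepted as table shell |
| `table_search_band_frac` | 0.3 | — | posterior image fraction searched for the shell |

Face connectivity is the conservative default: it cannot leak through a
diagonal one-voxel gap in the body wall. The air threshold is inclusive
on both the corner and table paths; the color thresholds are strict, so
a MIP pixel of exactly 2800 HU or a minIP pixel of exactly −220 HU stays
gray.

## Table-seed detection

The table scan is a concrete realization of a step the original
description leaves open. On each axial slice the central column is
scanned from the posterior border toward the body: leading air is
skipped, then the first contiguous run of above-threshold material (the
table shell); the voxel immediately behind it lies in the cavity and
becomes a seed. The scan then repeats inward from the left and right
borders at the cavity's height. Two guards prevent anatomy from being
misread as a table: runs thicker than `table_shell_max_mm` (the body
wall, a solid table) abort the scan, and the bottom scan searches only
the posterior `table_search_band_frac` of the image, where the table
physically sits. Seeds that land on above-threshold voxels are skipped,
not fatal. The scan is isolated behind one function so alternative
detectors can be swapped in.

## Numerical choices

- **Windowing** maps HU ≤ center − width/2 to 0 and HU ≥ center + width/2
  to 255, linearly in between, rounding half-up. The blend of rule 1 is
  computed in HU and windowed once; windowing the average before
  blending (mixing HU with display levels) was rejected as a unit error.
- **Empty minIP rays** (all voxels flagged, i.e. pure exterior air)
  return the sentinel +3071 HU — the top of the conventional HU range —
  so they can never satisfy the blue rule; infinity is avoided to keep
  images in valid HU range.
- **Anisotropic voxels**: the three projections are resampled to square
  pixels (the finer of the two spacings, separable linear interpolation)
  *before* thresholding/compositing, so color boundaries cannot bleed
  into interpolated fractional values. Isotropic input passes through
  unchanged, which keeps the phantom tests pixel-exact.
- **Degenerate inputs**: volumes must be ≥ 2 voxels per axis (corners
  distinct), finite, with positive spacing; an empty seed list yields an
  empty mask with a warning rather than an error.

## The phantom generator

Real PMCT data is confidential, so every stage is validated on
procedurally generated phantoms with exact ground truth: background air
(−1000 HU), a soft-tissue ellipsoid body (40 HU), bone-density rods
(1200 HU), metal spheres (3200 HU), enclosed gas pockets (−800 HU), and
an optional hollow table arc (shell 300 HU, cavity −1000 HU) whose
cavity is verified watertight by an independent flood fill at build
time. Painting proceeds background → table → body → bones → metal → gas,
later classes winning. Optional Gaussian noise is truncated at 3σ and
the spec is rejected unless 3σ stays below every class's distance to the
nearest decision threshold (−200, −220, 2800 HU), so ground-truth masks
remain exact under noise.

The standard fixtures (48×48×40 voxels, 1 mm isotropic) cover each
behaviour: `body_only`, `body_with_gas`, `body_with_metal`,
`body_with_hollow_table`, and `open_airway`, in which a gas channel
connects an interior gas region to the background — reproducing the
documented failure mode in which an uncompromised airway lets region
growing absorb the lungs, removing them from the gas visualization.

What the phantoms deliberately do **not** emulate: anatomy, hard-kernel
reconstruction noise texture, partial-volume effects at sub-resolution
structures, beam hardening and metal streaks, gantry tilt, or
non-watertight body surfaces. Passing tests therefore demonstrate the
algorithm's logic (segmentation topology, projection arithmetic,
compositing rules, I/O fidelity), not clinical image quality on real
scans.

## Verification strategy and problem sizes

Vectorized stages are checked against independently written brute-force
oracles: per-ray loops for all three projections (exact for extrema,
1e−9 for means) on random volumes ≤ 16³, and a breadth-first flood fill
for region growing on random volumes up to 32³ plus the table fixture.
On `body_with_gas` / `body_with_metal` the blue/red pixel sets must
equal the projected ground-truth footprints *exactly*; the hollow-table
fixture must render correctly only when table seeds are enabled; the
whole pipeline must be bit-identical across runs. These sizes keep the
full suite under a few seconds while exercising every code path.

## Known limitations

- Gas regions connected to the outside (open airways) are absorbed as
  exterior air and vanish from the visualization — inherent to the
  method, reproduced by the `open_airway` fixture.
- Superimposed projections can occlude findings (gas behind an aerated
  lung, fractures behind implants); the overview is a communication
  aid, not a substitute for slice-wise reading.
- Orthographic projection discards depth: object position requires the
  perpendicular view.
- The table detector assumes a thin-shelled table adjacent to the
  posterior border; exotic table geometries may need the two scan
  guards retuned, or table seeding disabled.
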