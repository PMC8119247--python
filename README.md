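# pmct-overview

Automated, color-coded 2D overview images from postmortem CT (PMCT)
volumes of the thorax/abdomen — for forensic institutes that need a
quick, fully automatic visual summary of a scan for briefings and image
reports: intracorporeal **gas** in blue, **radiopaque foreign bodies**
(implants, projectiles) in red, and bones/soft tissue as a gray
anatomical reference, in one image per view.

## Algorithm

Given a CT volume *V* in Hounsfield units:

1. **Exterior-air segmentation.** Region growing over
   {*v* : HU(*v*) ≤ −200} seeded at the eight volume corners (always
   outside the body) plus seeds detected inside the hollow, air-filled
   CT table, which the corner seeds cannot reach. The result *M* flags
   all air connected to the outside; gas enclosed in the body is left
   alone.
2. **Projections** per view (anterior-posterior and lateral,
   orthographic): MIP(*p*) = max ray HU, selective
   minIP(*p*) = min ray HU over voxels ∉ *M*, AVG(*p*) = mean ray HU.
3. **Compositing**, per pixel in order:
   - gray = window(0.7·MIP + 0.3·AVG), window center 500 HU / width 1000 HU;
   - if MIP > 2800 HU → pixel = (255, 0, 0);
   - if minIP < −220 HU → pixel = (0, 0, 255).
4. Export as 8-bit RGB PNG.

See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

No CT scan at hand? Generate a synthetic phantom — a soft-tissue body
with an enclosed gas pocket and a hollow air-filled table — and render
it:

```bash
pmct-overview phantom body_with_hollow_table --out demo.nii.gz
pmct-overview render --input demo.nii.gz --output-dir out --views ap,lateral
```

which prints:

```
wrote body_with_hollow_table (48x48x40) to demo.nii.gz
INFO pmct_overview.pipeline: loaded demo.nii.gz: shape=(48, 48, 40) spacing=(1.0, 1.0, 1.0)
INFO pmct_overview.pipeline: segmentation: 8 corner seeds, 120 table seeds, 73437 voxels flagged
rendered anterior_posterior, lateral -> out/demo_anterior_posterior.png, out/demo_lateral.png
```

The 8 corner seeds plus 120 table seeds (3 per axial slice: one from
the bottom scan, one each from the left and right) flag 73 437 voxels
of exterior air — background **and** the table cavity. Both PNGs show
the enclosed gas pocket as 49 pure-blue pixels (its exact projected
footprint) and no red, since this phantom has no metal. Re-run with
`--no-table-seeds` and the unreached table cavity is falsely rendered
blue — the reason the table seeds exist.

The same `render` command accepts a DICOM series directory instead of a
NIfTI file; `--save-mask` additionally writes the exterior-air mask as
NIfTI, and thresholds/weights/window are exposed as flags (see
`pmct-overview render --help`).

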