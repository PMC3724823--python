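# cnparcel

Microstructural parcellation of an arc-shaped subcortical nucleus (the
caudate) from diffusion MRI, with a fully synthetic validation path:

- **phantom** — a curved-nucleus DWI phantom: a tube swept along a planar
  circular arc, filled with tangential/radial fiber compartments whose
  volume-fraction schedule plants two known microstructural boundaries;
  multi-tensor signal simulation (b = 1000 s/mm², 60 directions by
  default) with Rician noise, plus a polarized-light-imaging (PLI)
  forward model.
- **tensor** — per-voxel log-linear diffusion-tensor fit, FA, principal
  directions, and direction-encoded RGB maps.
- **axis** — the core analysis: a longitudinal axis parameterized by the
  angle about an anterior-commissure landmark (polar centerline model),
  sampled at 45 points; the *radiality index* profile (mean angle between
  principal direction and axis tangent); group-level detection of the
  45° crossing and the head-adjacent local minimum; per-subject
  refinement within a 10 mm arc radius; tri-partition segmentation; and
  typical-subject selection from a deformation-cost matrix.
- **pli** — inverse PLI analysis: per-pixel sinusoid fitting over the two
  nine-image filter-rotation series (crossed / quarter-wave), recovering
  in-plane direction, inclination, and maximum-intensity maps.
- **tracking** — deterministic streamline tractography (500 seeds, 2 mm
  curvature radius, 30 mm minimum length, 0.05 amplitude cutoff by
  default) with inclusion/exclusion-mask bundle classification and
  per-subregion endpoint density maps.
- **io / pipeline / cli** — NIfTI, FSL bvec/bval, TCK, TIFF+JSON, CSV
  formats; a YAML-configured end-to-end driver; a `cnparcel` CLI.

## CLI

```sh
cnparcel phantom --out out/ph --snr 20 --seed 1     # synthetic DWI + truth
cnparcel tensor  --dwi out/ph/dwi.nii --bvec out/ph/dwi.bvec \
                 --bval out/ph/dwi.bval --mask out/ph/mask.nii --out out/t
cnparcel axis    --mask out/ph/mask.nii --tensors out/t --ac 0,0,0 \
                 --samples 45 --out out/axis
cnparcel segment --profiles out/axis/profile.csv --out out/seg
cnparcel track   --fa out/t/fa.nii --dirs out/t/principal_dir.nii \
                 --seed-mask out/ph/mask.nii --out out/trk
cnparcel bundles --tracks out/trk/streamlines.tck --rules rules.yaml --out out/b
cnparcel pli     --crossed c.tif c.json --quarter q.tif q.json --out out/pli
cnparcel run     --out out/full --seed 1            # whole pipeline on a phantom
```

Bundle rules are YAML: a `masks:` name→NIfTI mapping and ordered
`rules:` entries with `label`, `include` (list of groups; every group
must be visited, a group is satisfied by any of its masks) and `exclude`
(any hit rejects). First matching rule wins.

## Layout

```
src/cnparcel/
  core.py       gradient schemes, DWI container, voxel/world geometry
  phantom.py    curved-nucleus phantom, DWI + PLI forward simulation
  tensor.py     tensor fit, FA, RGB direction maps
  axis.py       longitudinal axis, radiality profile, boundaries, labels
  pli.py        sinusoid fitting, orientation/inclination maps, HSV export
  tracking.py   streamline tracking, bundle rules, endpoint densities
  io.py         NIfTI / bvec-bval / TCK / TIFF / CSV / JSON readers-writers
  pipeline.py   YAML config + end-to-end driver
  cli.py        click-based command line
```
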