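# cardiomar

Metal artifact detection and mask-conditioned 3D inpainting for
reconstructed cardiac CT.

Patients treated with stereotactic arrhythmia radiotherapy almost
always carry an implantable cardioverter-defibrillator, and the metal
leads throw bright streaks and dark shadows across the heart in CT.
Projection-domain artifact-reduction methods need the raw scanner data;
for images that exist only as reconstructed volumes the artifact must
be repaired in the image domain.  `cardiomar` implements a two-stage
pipeline for exactly that setting, aimed at researchers in cardiac
image analysis and radiotherapy planning:

1. **Detection** — a 2D encoder-decoder segments the artifact and the
   whole heart on each axial slice (artifacts are in-plane phenomena);
   the heart label in the loss keeps bone and airways, which share the
   artifacts' intensity range, from being flagged.
2. **Inpainting** — a 3D conditional GAN (pix2pix-style) refills the
   artifact region.  The generator sees the image with artifact voxels
   set to 0 HU plus the binary mask, and is trained with

   `L_G = w_adv · L_LSGAN + w_l1 · L1_mask + w_tv · TV(truth − pred)`,
   `w_tv = w_l1 / 2`,

   where `L1_mask` is evaluated inside the artifact mask only and the
   total-variation term on the difference image enforces a smooth
   transition at the mask border.  At inference the prediction is
   composited: voxels outside the mask are taken verbatim from the
   input.

Training pairs come from **artifact transplantation**: a segmented
artifact (mask + corrupted HU) is translated so donor and recipient
heart centers align, gated to within 3 voxels (4.5 mm at the 1.5 mm
working spacing) of the recipient heart, and copied into an
artifact-free recipient volume — the untouched recipient is the ground
truth.  A phantom generator (cardiac-like volumes with four chambers,
lungs, rib arcs, and lead-artifact corruption) supplies paired data so
the entire pipeline trains and evaluates without any acquired scans.
Evaluation compares chamber segmentations on the uncorrected,
0-HU-filled, and inpainted images against ground truth with surface
Dice, Dice, and mean/max/95th-percentile surface distances, plus
masked SSIM and masked L1 inside the artifact region.

## Worked example

The `demo` subcommand chains every stage — phantom synthesis,
transplantation (4 donors × 5 recipients; the 16 pairs of four
recipients train, the last recipient's 4 pairs are held out), detector
training, inpainter training, three-arm evaluation — from one seed:

```bash
cardiomar demo --seed 7 --out demo_out/
```

prints (abridged):

```
"uncorrected": { "surface_dice": 0.163482, "dice": 0.132376, "hd_mm": 19.073095, "masked_l1_hu": 583.315161 }
"solid_fill":  { "surface_dice": 0.822390, "dice": 0.645494, "hd_mm": 7.771548,  "masked_l1_hu": 183.119856 }
"inpainted":   { "surface_dice": 0.920170, "dice": 0.828177, "hd_mm": 4.140736,  "masked_l1_hu": 66.948673 }
detection: {'dice': 0.854548, 'tpr': 1.0, 'tnr': 0.999949}
```

Reading these: on the held-out cases the uncorrected artifact wrecks
automatic chamber segmentation (mean surface Dice 0.16 — the bright
artifact web fuses neighbouring chambers); overwriting the artifact
with 0 HU recovers much of it (0.82) but leaves holes where the
artifact crossed blood pool; the inpainted image is the best arm on
every metric (surface Dice 0.92, Hausdorff distance 4.1 mm, masked L1
67 HU against 183 HU for the solid fill).  The detector reaches Dice
0.85 against the ground-truth artifact mask on a held-out phantom with
perfect sensitivity inside the eroded contour (`tpr`) and near-perfect
specificity outside the 3-voxel margin (`tnr`).  `demo_out/reports/`
contains the per-case long-format CSV and the JSON summary; rerunning
with the same seed reproduces both byte for byte.

Each stage is also available separately (`synth-phantoms`,
`transplant`, `train-detect`, `detect`, `train-inpaint`, `inpaint`,
`evaluate`) and as a library:

```python
from cardiomar import (InpaintConfig, InpaintingModel, make_case)

cases = [make_case(seed) for seed in range(8)]
results = InpaintingModel(cases, InpaintConfig.toy(seed=7)).fit()
print(results.summary())
fixed = results.inpaint(cases[0].corrupted, cases[0].artifact_mask)
```

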