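# Methods

`cardiomar` implements two-stage metal artifact reduction (MAR) for
already-reconstructed cardiac CT: a slice-wise 2D network detects the
streak/shadow artifacts that implanted device leads produce, and a 3D
mask-conditioned generative network refills the detected region with
anatomically consistent Hounsfield values.  Because no acquired data
ship with the package, a phantom generator supplies the study
conditions under which every stage is trained and scored.  This note
records the models, the parameters that matter, the numerical choices,
and what the phantom experiments do and do not demonstrate.

## Image model and conventions

Volumes are axis-aligned grids of Hounsfield units (HU) with per-axis
spacing in mm; arrays are indexed `(x, y, z)` in RAS orientation and an
axial slice is `voxels[:, :, k]`.  Files are NIfTI-1; masks are stored
as uint8 {0,1}; on load HU are clamped to the 12-bit CT range
[-1024, 3071] so sentinel values cannot skew losses.  All cross-case
operations (transplantation, pixel-specified margins, metrics) are
meant to run on a common 1.5 mm isotropic working grid, on which the
recurring "3 pixel" tolerance equals 4.5 mm; `resample_isotropic`
(linear for images, nearest for masks) produces that grid.

"N pixel" morphology is deliberately split by use: erosion margins use
N iterations of the full 3×3×3 neighbourhood (matching how a margin is
peeled off a manual contour), while dilation gates and distance
tolerances use a Euclidean distance threshold of N voxels (matching
surface metrics).  Both elements are exposed as arguments.

## Artifact detection

The detector is a 2D U-shaped encoder-decoder (instance normalization,
leaky-ReLU, strided-conv downsampling, nearest-upsample + conv
decoding with skip concatenation) applied to axial slices and restacked
to 3D, because lead artifacts live almost entirely in-plane.  Slices
are windowed to [-1000, 2000] HU and mapped affinely to [-1, 1].

The loss is cross-entropy plus soft Dice over **three** mutually
exclusive classes: background, whole heart, artifact.  Supervising the
heart alongside the artifact is the load-bearing trick: bone and
airways share the artifacts' intensity range, and the heart channel
teaches the network where artifacts can plausibly occur.  Setting
`include_heart=False` trains the identical architecture as a two-class
segmenter and serves as the ablation arm; on phantoms with rib arcs the
three-class model produces roughly fifty-fold fewer artifact false
positives on bone (means over three seeds in the acceptance suite).
Training slices are drawn 2/3 from slices containing artifact and 1/3
uniformly, since artifacts are sparse and a toy budget cannot wait for
balance to emerge.  Exact probability ties at the argmax resolve in
favour of the rarer class (artifact > heart > background).

## Paired data by artifact transplantation

Supervised inpainting needs corrupted/clean pairs, which patient scans
cannot provide.  Pairs are synthesized by transplantation: a donor case
contributes its artifact mask and the corrupted HU beneath it; both are
translated (whole voxels, no rotation or scaling) so the donor and
recipient heart centers of mass coincide; artifact voxels within 3
voxels (Euclidean) of the recipient heart survive the gate and their
corrupted HU are copied verbatim into the recipient volume.  The
untouched recipient is the ground truth, so `synthetic == ground_truth`
holds bit-for-bit outside the placed mask — an invariant the tests
check exactly, not approximately.  Donor voxels shifted off-grid are
dropped and logged; a case whose gated mask comes out empty is flagged
unusable rather than raising, so dataset construction survives odd
pairings.

## Inpainting model

The generator is a 3D U-shaped encoder-decoder in the conditional-GAN
(pix2pix) mould with two input channels — the image with artifact
voxels overwritten to 0 HU, and the binary artifact mask — and a tanh
head predicting the artifact-free patch in normalized units.  The
full-scale configuration (80×80×32 patches, four encoder and four
decoder stages, base width 15) carries ≈4.7 M generator parameters.
The discriminator is a 3-level strided 3D conv stack scoring
(conditioning ⊕ candidate) patches (least-squares GAN).

The generator objective is

    L_G = w_adv · L_LSGAN + w_l1 · L1_mask + w_tv · TV(truth − pred)

with `L1_mask` the mean absolute error **inside the artifact mask
only** (outside the mask the composited output is exact by
construction, so residuals there carry no signal), and the total
variation computed **on the difference image** so that a constant bias
costs nothing while a seam at the mask border is penalized — it is the
transition smoothness term.  `w_tv` defaults to half of `w_l1`; the
weight tie is contract-tested.  Defaults `w_adv : w_l1 = 1 : 100`
follow the pix2pix convention; losses are computed in normalized
intensity units, so the weights are scale-free.  Optimization is Adam
(lr 2e-4, β₁ 0.5); the CPU-scale `toy()` configuration (32×32×16
patches, 3+3 stages, base width 6) raises the learning rate to 5e-4,
which is stable at that size and compensates for the short epoch
budget.

Patches are centered on artifact connected components with seeded
jitter, and extra patches are appended until every artifact voxel is
covered.  At inference the prediction is de-normalized, clamped to the
HU window, averaged where patch footprints overlap inside the mask,
and composited: output = input outside the mask, prediction inside.
The compositing contract (bit-exact passthrough outside the mask, for
any generator state) is tested with untrained generators.

All networks run on `cardiomar.nnet`, a compact numpy reverse-mode
autodiff engine written for this package: convolution via offset-slice
im2col so inner loops are BLAS matrix products, and finite-difference
gradient checks in the test suite for every primitive.  Pure-numpy
execution makes seeded training bit-reproducible at a fixed thread
count, which the end-to-end determinism test relies on.

## Phantom study conditions

`make_phantom` emulates what a contrast cardiac CT shows around the
heart: soft tissue 40 HU, lung fields −800 HU, an ellipsoidal heart
with myocardium 100 HU, four blood-pool chambers at 300 HU separated
by ≈3-voxel (4.5 mm) septal walls, rib-like bone arcs at 700 HU, and
10 HU Gaussian noise; geometry is jittered per seed.  The default grid
is 64×64×32 at 1.5 mm so the full pipeline runs in CPU minutes.

`make_artifact` reproduces the morphology of lead artifacts: a bright
cylindrical core (the wire plus blooming, in-plane radius 4.5 voxels)
running across several slices **along a chamber wall** — device leads
hug the septum, and wall-adjacent placement is what makes artifacts
obscure anatomical borders — plus in-plane bright (+600 HU) and shadow
(−600 HU) streaks radiating from the lead, all clipped to the 3-voxel
heart gate.  Bright streaks overlap the bone palette on purpose; that
overlap is what gives the heart-in-loss ablation its bite.  Offsets
are applied exactly (no re-noising), so `corrupted − clean` is
precisely ±offset inside the mask and zero outside.

What the phantom does **not** emulate: CT physics (no sinogram,
beam-hardening or photon-starvation modelling — streaks are painted,
not reconstructed), respiratory/cardiac motion, anatomical variability
beyond ellipsoid jitter, and scanner noise texture (white Gaussian
only).  Passing the phantom study therefore shows that the pipeline's
mechanics are correct and that the learning problems are solvable under
idealized geometry; it does not certify performance on patient images.

## Evaluation

Metrics: Dice (both-empty pairs count as 1), surface Dice at a 3-voxel
tolerance (one-empty pairs count as 0), and mean / maximum / 95th
percentile of the pooled symmetric surface-to-surface distances in mm,
all computed with exact Euclidean distance transforms and verified
against all-pairs brute-force oracles to 1e-9 on random masks.
Detection adds TPR inside the 3-voxel-eroded manual contour (its
uncertain border removed) and TNR outside the 3-voxel-dilated contour;
the TNR denominator is every grid voxel beyond the margin — the
simplest defensible reading, not restricted to a body mask.  Masked
SSIM uses a 3D Gaussian window (σ = 1.5 voxels, K1 = 0.01, K2 = 0.03,
data range = HU window width) averaged inside the artifact mask.

The three-arm harness mirrors clinical judgement of a MAR fix: segment
the chambers on (a) the uncorrected image, (b) a 0-HU solid fill, and
(c) the inpainted image with one deterministic reference segmenter,
then score each arm against ground-truth chamber masks — only for
chambers the artifact actually touches, since untouched chambers carry
no signal about the fix.

The reference segmenter stands in for a third-party multi-label
chamber tool.  It thresholds blood pool (> 200 HU inside the heart
mask) and then splits pools the way a marker-controlled tool does:
a 3×3×3 morphological opening erases thin streaks and cuts hairline
bridges to form seed regions, seeds are labeled, and every remaining
blood-pool voxel joins its nearest seed.  The design point is that a
multi-label tool cannot lose a chamber to component bookkeeping — a
one-voxel bleed across a wall must not zero out a chamber — while a
genuinely thick corruption web fusing two pools is a real failure and
stays fused.  On clean phantoms the segmenter reproduces the chambers
with Dice 1.0; on corrupted phantoms it degrades sharply, which is the
premise of the whole comparison.

Under these conditions the toy study reproduces the qualitative
ordering the method is built to achieve: inpainting > solid fill >
uncorrected on mean surface Dice, and inpainting < solid fill on
masked L1.  The solid-fill arm beats the uncorrected arm because the
bright core webs fuse chambers in the uncorrected image, while a 0-HU
fill merely carves recoverable holes; inpainting beats both because it
restores the wall/pool geometry the segmenter needs.

## Scale of the shipped experiments

The end-to-end study uses 4 donor × 5 recipient phantoms (16 training
transplants, 4 held-out on an unseen recipient), a 10-epoch detector
(~110 k parameters) and a 30-epoch toy inpainter (~186 k parameters) —
sizes chosen so the whole study, run twice for the bit-reproducibility
check, completes in CPU minutes.  The full-scale configuration
(80×80×32, ≈4.7 M parameters) is constructed and contract-tested but
not trained by the shipped experiments.

## Known limitations

- Translation-only heart alignment; rotation/scale mismatch between
  donor and recipient is not corrected (and does not arise between
  phantoms of the same family).
- Streak painting is not CT-physics-accurate; a model trained on
  painted streaks should not be expected to transfer to real ICD
  artifacts without retraining on transplanted patient artifacts.
- The inpainter's output is smoother than real CT texture; no noise
  re-injection is attempted.
- The toy GAN can still leave an occasional >2-voxel bleed across a
  thin wall, which the reference segmenter then counts as a fused —
  failed — chamber; the shipped study's inpainted arm includes such a
  case and wins on the mean regardless.
- Oblique NIfTI affines are reduced to the closest canonical axes;
  true oblique geometry is out of scope.
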