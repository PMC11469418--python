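"""Mask-conditioned 3D inpainting of artifact regions with a patch GAN.

The generator is a 3D U-shaped encoder-decoder in the conditional-GAN
(pix2pix) mould.  It sees two channels — the image with the artifact
voxels overwritten to 0 HU, and the binary artifact mask — and predicts
the artifact-free image.  Training minimizes an adversarial term from a
3D patch discriminator, an L1 term computed only on artifact voxels,
and a total-variation term on the (truth - prediction) difference image
weighted half as strongly as the L1 term, which forces the inpainted
region to blend smoothly into its untouched surroundings.  At inference
the prediction is composited: voxels outside the artifact mask are taken
verbatim from the input, so only the artifact region is ever altered.

Usage follows a fit/results pattern::

    model = InpaintingModel(cases, InpaintConfig.toy(seed=7))
    results = model.fit()
    fixed = results.inpaint(volume, artifact_mask)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import BinaryMask, CTVolume, PhantomCase
from .nnet import Adam, PatchDiscriminator, Tensor, UNet, concat


@dataclass
class InpaintConfig:
    """Architecture, loss weights and training settings.

    Defaults describe the full-scale model: 80x80x32 patches, four
    encoder and four decoder stages (~4.8 M generator parameters), and
    an L1:TV weight ratio of 2:1 (``w_tv`` defaults to half ``w_l1``).
    :meth:`toy` gives a configuration sized for CPU-minute training.
    """

    patch_size: tuple[int, int, int] = (80, 80, 32)
    enc_layers: int = 4
    dec_layers: int = 4
    base_channels: int = 15
    w_adv: float = 1.0
    w_l1: float = 100.0
    w_tv: float | None = None  # defaults to 0.5 * w_l1
    epochs: int = 20
    lr: float = 2e-4
    batch: int = 2
    seed: int = 0
    hu_window: tuple[float, float] = (-1000.0, 2000.0)
    disc_channels: int = 8
    disc_levels: int = 3
    max_width: int | None = None
    patch_jitter_vox: int = 2

    def __post_init__(self) -> None:
        if self.w_tv is None:
            self.w_tv = 0.5 * self.w_l1
        if self.w_l1 <= 0 or self.w_tv < 0:
            raise ValueError("w_l1 must be positive and w_tv non-negative")
        if self.enc_layers != self.dec_layers:
            raise ValueError("encoder and decoder stage counts must match")
        div = 2**self.enc_layers
        if any(p % div for p in self.patch_size):
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^enc_layers={div}"
            )

    @classmethod
    def toy(cls, **kw) -> "InpaintConfig":
        """CPU-scale configuration: 32x32x16 patches, 3+3 stages.

        The raised learning rate compensates for the short epoch budget
        of a CPU run; at this scale training is stable well above the
        full-scale default.
        """
        kw.setdefault("patch_size", (32, 32, 16))
        kw.setdefault("enc_layers", 3)
        kw.setdefault("dec_layers", 3)
        kw.setdefault("base_channels", 6)
        kw.setdefault("epochs", 30)
        kw.setdefault("lr", 5e-4)
        return cls(**kw)


@dataclass
class Patch:
    """A training patch: masked input, mask channel, target, placement."""

    input_ch1: np.ndarray  # HU, artifact voxels set to 0
    input_ch2: np.ndarray  # binary artifact mask
    target: np.ndarray  # ground-truth HU
    offset: tuple[int, int, int]


# ---------------------------------------------------------------------------
# Losses and plain array operations


def solid_fill(vol: CTVolume, mask: BinaryMask, fill_hu: float = 0.0) -> CTVolume:
    """Overwrite masked voxels with a constant HU (the baseline fix)."""
    out = vol.voxels.copy()
    out[mask.voxels] = fill_hu
    return CTVolume(out, vol.spacing, vol.origin)


def masked_l1(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute difference over the masked voxels only."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != target.shape or pred.shape != mask.shape:
        raise ValueError("shapes must match")
    n = int(mask.sum())
    if n == 0:
        warnings.warn("masked_l1 over an empty mask is defined as 0", stacklevel=2)
        return 0.0
    return float(np.abs(pred[mask] - target[mask]).mean())


def tv_on_difference(pred: np.ndarray, target: np.ndarray) -> float:
    """Anisotropic total variation of the difference image d = target - pred.

    Mean absolute forward difference over all axes; a constant offset has
    zero TV, so this term penalizes seams, not bias.
    """
    d = np.asarray(target, dtype=np.float64) - np.asarray(pred, dtype=np.float64)
    total = 0.0
    n_terms = 0
    for ax in range(d.ndim):
        if d.shape[ax] < 2:
            continue
        sl_hi = [slice(None)] * d.ndim
        sl_lo = [slice(None)] * d.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        diff = d[tuple(sl_hi)] - d[tuple(sl_lo)]
        total += float(np.abs(diff).sum())
        n_terms += diff.size
    return total / n_terms if n_terms else 0.0


def _masked_l1_t(pred: Tensor, target: Tensor, mask: np.ndarray) -> Tensor:
    m = Tensor(mask.astype(np.float32))
    n = float(mask.sum())
    return ((pred - target) * m).abs().sum() * (1.0 / max(n, 1.0))


def _tv_t(pred: Tensor, target: Tensor) -> Tensor:
    d = target - pred
    nd = d.data.ndim
    total = None
    n_terms = 0
    for ax in range(2, nd):
        if d.data.shape[ax] < 2:
            continue
        hi = [slice(None)] * nd
        lo = [slice(None)] * nd
        hi[ax] = slice(1, None)
        lo[ax] = slice(None, -1)
        diff = d[tuple(hi)] - d[tuple(lo)]
        term = diff.abs().sum()
        total = term if total is None else total + term
        n_terms += diff.data.size
    if total is None:
        return Tensor(0.0)
    return total * (1.0 / n_terms)


# ---------------------------------------------------------------------------
# Patch extraction


def _clip_offset(center, patch, shape):
    off = []
    for c, p, s in zip(center, patch, shape):
        if s < p:
            raise ValueError(f"volume dimension {s} smaller than patch {p}")
        off.append(int(np.clip(round(c - p / 2), 0, s - p)))
    return tuple(off)


def extract_patches(case, cfg: InpaintConfig, seed: int | None = None) -> list[Patch]:
    """Patches centered on artifact components, jittered, covering the mask.

    ``case`` needs ``corrupted``/``artifact_mask``/``clean`` (a
    :class:`PhantomCase` or transplant result viewed as one).  Patch
    centers start at connected-component centroids with a little seeded
    jitter; extra patches are appended until every artifact voxel lies in
    at least one patch footprint.
    """
    corrupted = case.corrupted.voxels
    clean = case.clean.voxels
    mask = case.artifact_mask.voxels
    if not mask.any():
        warnings.warn("empty artifact mask: no patches extracted", stacklevel=2)
        return []
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = mask.shape
    p = cfg.patch_size

    ch1_full = corrupted.copy()
    ch1_full[mask] = 0.0

    labels, n = ndimage.label(mask)
    offsets = []
    for centroid in ndimage.center_of_mass(mask, labels, range(1, n + 1)):
        c = [ci + rng.integers(-cfg.patch_jitter_vox, cfg.patch_jitter_vox + 1)
             for ci in centroid]
        offsets.append(_clip_offset(c, p, shape))

    covered = np.zeros(shape, dtype=bool)
    for off in offsets:
        sl = tuple(slice(o, o + pi) for o, pi in zip(off, p))
        covered[sl] = True
    uncovered = mask & ~covered
    while uncovered.any():
        c = np.argwhere(uncovered)[0]
        off = _clip_offset(c, p, shape)
        offsets.append(off)
        sl = tuple(slice(o, o + pi) for o, pi in zip(off, p))
        covered[sl] = True
        uncovered = mask & ~covered

    patches = []
    for off in offsets:
        sl = tuple(slice(o, o + pi) for o, pi in zip(off, p))
        patches.append(
            Patch(
                input_ch1=ch1_full[sl].copy(),
                input_ch2=mask[sl].copy(),
                target=clean[sl].copy(),
                offset=off,
            )
        )
    return patches


# ---------------------------------------------------------------------------
# Model


def _norm(v: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (2.0 * (np.clip(v, lo, hi) - lo) / (hi - lo) - 1.0).astype(np.float32)


def _denorm(v: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return np.clip((v + 1.0) / 2.0 * (hi - lo) + lo, lo, hi).astype(np.float32)


def build_inpainter(cfg: InpaintConfig) -> tuple[UNet, PatchDiscriminator]:
    """Seeded generator + discriminator pair for a configuration."""
    gen = UNet(
        3, 2, 1, cfg.base_channels, cfg.enc_layers,
        np.random.default_rng(cfg.seed + 11), head="tanh",
        max_width=cfg.max_width,
    )
    disc = PatchDiscriminator(
        3, 3, cfg.disc_channels, np.random.default_rng(cfg.seed + 13),
        levels=cfg.disc_levels,
    )
    return gen, disc


class InpaintingModel:
    """Conditional-GAN inpainting model built from paired cases.

    ``cases`` may be :class:`PhantomCase` objects (with corrupted volume
    and artifact mask) or pre-extracted :class:`Patch` lists.
    """

    def __init__(self, cases, config: InpaintConfig | None = None):
        self.config = config or InpaintConfig.toy()
        cfg = self.config
        self.patches: list[Patch] = []
        for i, c in enumerate(cases):
            if isinstance(c, Patch):
                self.patches.append(c)
            else:
                self.patches.extend(extract_patches(c, cfg, seed=cfg.seed + 7 * i))
        if not any(p.input_ch2.any() for p in self.patches):
            raise ValueError("no artifact voxels in any training patch")

    def fit(self) -> "InpaintingResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        gen, disc = build_inpainter(cfg)
        opt_g = Adam(gen.parameters(), lr=cfg.lr, beta1=0.5)
        opt_d = Adam(disc.parameters(), lr=cfg.lr, beta1=0.5)

        xs = np.stack(
            [
                np.stack([_norm(p.input_ch1, cfg.hu_window),
                          p.input_ch2.astype(np.float32)])
                for p in self.patches
            ]
        )
        ys = np.stack([_norm(p.target, cfg.hu_window)[None] for p in self.patches])
        masks = np.stack([p.input_ch2[None].astype(bool) for p in self.patches])

        history = {"d": [], "g_adv": [], "g_l1": [], "g_tv": [], "g": []}
        n = len(self.patches)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            ep = {k: 0.0 for k in history}
            n_batches = 0
            for b0 in range(0, n, cfg.batch):
                idx = order[b0 : b0 + cfg.batch]
                x = Tensor(xs[idx])
                y = Tensor(ys[idx])
                m = masks[idx]

                fake = gen(x)

                # Discriminator update on (conditioning, candidate) pairs.
                disc.zero_grad()
                d_real = disc(concat([x, y], axis=1))
                d_fake = disc(concat([x, fake.detach()], axis=1))
                loss_d = ((d_real - 1.0) * (d_real - 1.0)).mean() * 0.5 + (
                    d_fake * d_fake
                ).mean() * 0.5
                loss_d.backward()
                opt_d.step()

                # Generator update: adversarial + masked L1 + TV-on-difference.
                gen.zero_grad()
                disc.zero_grad()
                d_fake2 = disc(concat([x, fake], axis=1))
                adv = ((d_fake2 - 1.0) * (d_fake2 - 1.0)).mean() * 0.5
                l1 = _masked_l1_t(fake, y, m)
                tv = _tv_t(fake, y)
                loss_g = cfg.w_adv * adv + cfg.w_l1 * l1 + cfg.w_tv * tv
                loss_g.backward()
                opt_g.step()

                ep["d"] += float(loss_d.data)
                ep["g_adv"] += float(adv.data)
                ep["g_l1"] += float(l1.data)
                ep["g_tv"] += float(tv.data)
                ep["g"] += float(loss_g.data)
                n_batches += 1
            for k in history:
                history[k].append(ep[k] / n_batches)
        return InpaintingResults(gen, disc, cfg, history)


class InpaintingResults:
    """A fitted inpainting model with compositing inference."""

    def __init__(self, generator: UNet, discriminator, config: InpaintConfig,
                 history: dict[str, list[float]]):
        self.generator = generator
        self.discriminator = discriminator
        self.config = config
        self.history = history

    def inpaint(self, vol: CTVolume, mask: BinaryMask) -> CTVolume:
        """Refill the masked region; outside the mask the input passes through.

        Patches covering the mask are predicted independently; where
        footprints overlap inside the mask the predictions are averaged.
        The composited output is exactly the input outside the mask.
        """
        return inpaint(self.generator, vol, mask, self.config)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Mask-conditioned 3D inpainting GAN",
            f"  generator parameters: {self.generator.n_parameters():,}",
            f"  patch size: {self.config.patch_size}, "
            f"stages: {self.config.enc_layers}+{self.config.dec_layers}",
            f"  loss weights: adv {self.config.w_adv}, L1 {self.config.w_l1}, "
            f"TV {self.config.w_tv}",
            f"  epochs: {len(h['g'])}  masked L1 (norm. units): "
            f"{h['g_l1'][0]:.4f} -> {h['g_l1'][-1]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"g{i}": a for i, a in enumerate(self.generator.state_arrays())}
        arrays.update(
            {f"d{i}": a for i, a in enumerate(self.discriminator.state_arrays())}
        )
        np.savez_compressed(path, **arrays)
        cfg = asdict(self.config)
        path.with_suffix(".json").write_text(
            json.dumps({"config": cfg, "history": self.history}, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "InpaintingResults":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        raw = dict(sidecar["config"])
        for key in ("patch_size", "hu_window"):
            raw[key] = tuple(raw[key])
        cfg = InpaintConfig(**raw)
        gen, disc = build_inpainter(cfg)
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        with np.load(npz_path) as z:
            gen.load_state_arrays(
                [z[f"g{i}"] for i in range(len(gen.parameters()))]
            )
            disc.load_state_arrays(
                [z[f"d{i}"] for i in range(len(disc.parameters()))]
            )
        return cls(gen, disc, cfg, sidecar["history"])


def inpaint(generator: UNet, vol: CTVolume, mask: BinaryMask,
            cfg: InpaintConfig) -> CTVolume:
    """Composited inpainting of a whole volume (see InpaintingResults.inpaint)."""
    if not mask.voxels.any():
        return vol.copy()
    shell = PhantomCase(
        clean=vol, corrupted=vol, artifact_mask=mask,
        heart_mask=mask, chamber_masks={},
    )
    patches = extract_patches(shell, cfg, seed=cfg.seed)
    acc = np.zeros(vol.shape, dtype=np.float64)
    cnt = np.zeros(vol.shape, dtype=np.int32)
    for p in patches:
        x = np.stack([_norm(p.input_ch1, cfg.hu_window),
                      p.input_ch2.astype(np.float32)])[None]
        pred = generator(Tensor(x)).data[0, 0]
        hu = _denorm(pred, cfg.hu_window)
        sl = tuple(slice(o, o + s) for o, s in zip(p.offset, cfg.patch_size))
        acc[sl] += hu
        cnt[sl] += 1
    out = vol.voxels.copy()
    inside = mask.voxels & (cnt > 0)
    out[inside] = (acc[inside] / cnt[inside]).astype(np.float32)
    return CTVolume(out, vol.spacing, vol.origin)
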