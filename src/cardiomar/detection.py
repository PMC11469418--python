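"""Slice-wise 2D segmentation of metal artifacts and the whole heart.

Streak artifacts from device leads live mainly in the axial planes, so
the detector is a 2D encoder-decoder trained on axial slices and applied
slice by slice, the per-slice label maps stacked back into 3D masks.
The whole heart is carried as a third class in the loss alongside
background and artifact: supervising the heart teaches the network where
artifacts can plausibly live and keeps bright bone and dark airways —
which share the artifacts' intensity range — from being flagged as
artifacts.  Setting ``include_heart=False`` trains the same network as a
plain background/artifact segmenter, which is the ablation arm.

The model object follows a fit/results pattern::

    results = ArtifactDetector(cases, DetectionConfig(seed=7)).fit()
    pred = results.detect(volume)     # DetectionPrediction
    print(results.summary())
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import BinaryMask, CTVolume, PhantomCase
from .nnet import Adam, Tensor, UNet


@dataclass
class DetectionConfig:
    """Architecture and training settings for the artifact detector.

    ``in_plane_patch`` must be divisible by ``2**depth``; ``hu_window``
    is the intensity window (HU) mapped affinely to [-1, 1] before the
    network sees a slice.  ``artifact_slice_fraction`` is the share of
    training slices drawn from slices that contain artifact voxels (the
    rest are drawn uniformly).
    """

    in_plane_patch: tuple[int, int] = (64, 64)
    base_channels: int = 8
    depth: int = 3
    epochs: int = 10
    iters_per_epoch: int = 30
    lr: float = 1e-3
    batch: int = 4
    seed: int = 0
    hu_window: tuple[float, float] = (-1000.0, 2000.0)
    include_heart: bool = True
    artifact_slice_fraction: float = 2.0 / 3.0
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window must satisfy lo < hi")
        div = 2**self.depth
        if any(p % div for p in self.in_plane_patch):
            raise ValueError(
                f"in_plane_patch {self.in_plane_patch} not divisible by 2^depth={div}"
            )

    @property
    def n_classes(self) -> int:
        return 3 if self.include_heart else 2


@dataclass
class DetectionPrediction:
    """Stacked per-slice prediction: probabilities and argmax masks."""

    artifact_mask: BinaryMask
    heart_mask: BinaryMask | None
    probabilities: np.ndarray  # (n_classes, nx, ny, nz), sums to 1 per voxel


def _normalize(vox: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (2.0 * (np.clip(vox, lo, hi) - lo) / (hi - lo) - 1.0).astype(np.float32)


def _softmax_losses(logits: Tensor, onehot: np.ndarray, weights: np.ndarray):
    """Weighted cross-entropy + soft Dice over classes, as graph tensors."""
    zmax = logits.data.max(axis=1, keepdims=True)  # constant for stability
    z = logits - Tensor(zmax)
    lse = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - lse
    wmap = Tensor((onehot * weights.reshape(1, -1, 1, 1)).astype(np.float32))
    ce = -(logp * wmap).sum() * (1.0 / onehot[:, 0].size)
    p = logp.exp()
    y = Tensor(onehot)
    inter = (p * y).sum(axis=(0, 2, 3))
    sizes = p.sum(axis=(0, 2, 3)) + Tensor(onehot.sum(axis=(0, 2, 3)))
    dice = (inter * 2.0 + 1.0) / (sizes + 1.0)
    wsum = float(weights.sum())
    soft_dice_loss = 1.0 - (dice * Tensor(weights)).sum() * (1.0 / max(wsum, 1e-8))
    return ce, soft_dice_loss


class ArtifactDetector:
    """2D artifact + heart segmentation model built from paired cases.

    ``cases`` is a list of :class:`PhantomCase` (or any object carrying
    ``corrupted``/``heart_mask``/``artifact_mask``); slices are sampled
    across all cases during :meth:`fit`.
    """

    def __init__(self, cases: list[PhantomCase], config: DetectionConfig | None = None):
        self.config = config or DetectionConfig()
        if not cases:
            raise ValueError("need at least one training case")
        self._volumes = []
        self._labels = []
        for c in cases:
            vol = c.corrupted if c.corrupted is not None else c.clean
            lab = np.zeros(vol.shape, dtype=np.int64)
            if self.config.include_heart:
                lab[c.heart_mask.voxels] = 1
                if c.artifact_mask is not None:
                    lab[c.artifact_mask.voxels] = 2
            elif c.artifact_mask is not None:
                lab[c.artifact_mask.voxels] = 1
            self._volumes.append(_normalize(vol.voxels, self.config.hu_window))
            self._labels.append(lab)
        self._spacing = cases[0].clean.spacing
        art_class = self.config.n_classes - 1
        if not any((lab == art_class).any() for lab in self._labels):
            raise ValueError("no artifact voxels anywhere in the training data")

    def _sample_slices(self, rng) -> list[tuple[int, int]]:
        art_class = self.config.n_classes - 1
        art, all_ = [], []
        for ci, lab in enumerate(self._labels):
            for z in range(lab.shape[2]):
                all_.append((ci, z))
                if (lab[:, :, z] == art_class).any():
                    art.append((ci, z))
        picks = []
        for _ in range(self.config.batch):
            pool = art if (art and rng.uniform() < self.config.artifact_slice_fraction) else all_
            picks.append(pool[int(rng.integers(len(pool)))])
        return picks

    def _crop(self, arr2d: np.ndarray, rng=None):
        px, py = self.config.in_plane_patch
        nx, ny = arr2d.shape[:2]
        if (nx, ny) == (px, py):
            return arr2d
        if nx < px or ny < py:
            pad = ((0, max(0, px - nx)), (0, max(0, py - ny)))
            pad += ((0, 0),) * (arr2d.ndim - 2)
            arr2d = np.pad(arr2d, pad)
            nx, ny = arr2d.shape[:2]
        x0 = int(rng.integers(nx - px + 1)) if rng is not None else (nx - px) // 2
        y0 = int(rng.integers(ny - py + 1)) if rng is not None else (ny - py) // 2
        return arr2d[x0 : x0 + px, y0 : y0 + py]

    def fit(self) -> "DetectionResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = UNet(2, 1, cfg.n_classes, cfg.base_channels, cfg.depth,
                   np.random.default_rng(cfg.seed + 1))
        opt = Adam(net.parameters(), lr=cfg.lr, beta1=0.9)
        weights = np.asarray(
            cfg.class_weights if cfg.class_weights is not None
            else (1.0,) * cfg.n_classes,
            dtype=np.float32,
        )
        if len(weights) != cfg.n_classes:
            raise ValueError("class_weights length must match the class count")

        history = []
        for _ in range(cfg.epochs):
            epoch_loss = 0.0
            for _ in range(cfg.iters_per_epoch):
                picks = self._sample_slices(rng)
                imgs, labs = [], []
                for ci, z in picks:
                    joint = np.concatenate(
                        [
                            self._volumes[ci][:, :, z][..., None],
                            self._labels[ci][:, :, z][..., None].astype(np.float32),
                        ],
                        axis=-1,
                    )
                    joint = self._crop(joint, rng)
                    imgs.append(joint[..., 0])
                    labs.append(joint[..., 1].astype(np.int64))
                x = Tensor(np.stack(imgs)[:, None])
                lab = np.stack(labs)
                onehot = np.eye(cfg.n_classes, dtype=np.float32)[lab]
                onehot = np.moveaxis(onehot, -1, 1)
                net.zero_grad()
                logits = net(x)
                ce, sd = _softmax_losses(logits, onehot, weights)
                loss = ce + sd
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
            history.append(epoch_loss / cfg.iters_per_epoch)
        return DetectionResults(net, cfg, history, self._spacing)


class DetectionResults:
    """A fitted detector: weights, training diagnostics, and inference."""

    def __init__(self, net: UNet, config: DetectionConfig,
                 loss_history: list[float], train_spacing):
        self.net = net
        self.config = config
        self.loss_history = list(loss_history)
        self.train_spacing = tuple(train_spacing)

    def predict_proba(self, vol: CTVolume, batch: int = 8) -> np.ndarray:
        """Per-class probability volume of shape (n_classes, nx, ny, nz)."""
        if self.train_spacing and not np.allclose(
            vol.spacing, self.train_spacing, rtol=0.25
        ):
            warnings.warn(
                f"volume spacing {vol.spacing} differs from training spacing "
                f"{self.train_spacing}; predictions may degrade",
                stacklevel=2,
            )
        norm = _normalize(vol.voxels, self.config.hu_window)
        nz = norm.shape[2]
        probs = np.empty((self.config.n_classes,) + vol.shape, dtype=np.float32)
        for z0 in range(0, nz, batch):
            sl = norm[:, :, z0 : z0 + batch]
            x = Tensor(np.moveaxis(sl, -1, 0)[:, None])
            logits = self.net(x).data
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            p = e / e.sum(axis=1, keepdims=True)
            probs[:, :, :, z0 : z0 + batch] = np.moveaxis(p, 0, -1)
        return probs

    def detect(self, vol: CTVolume) -> DetectionPrediction:
        """Segment every axial slice and stack the results into 3D masks.

        Exact probability ties at the argmax resolve in favour of the
        rarer class (artifact > heart > background).
        """
        probs = self.predict_proba(vol)
        priority = np.arange(self.config.n_classes)[::-1]  # artifact first
        label = priority[np.argmax(probs[priority], axis=0)]
        art_class = self.config.n_classes - 1
        artifact = BinaryMask(label == art_class, vol.spacing, vol.origin)
        heart = (
            BinaryMask(label == 1, vol.spacing, vol.origin)
            if self.config.include_heart
            else None
        )
        return DetectionPrediction(artifact, heart, probs)

    def summary(self) -> str:
        lines = [
            "Artifact detection model (2D slice-wise encoder-decoder)",
            f"  classes: {self.config.n_classes} "
            f"({'background/heart/artifact' if self.config.include_heart else 'background/artifact'})",
            f"  parameters: {self.net.n_parameters():,}",
            f"  epochs: {len(self.loss_history)}  "
            f"final loss: {self.loss_history[-1]:.4f}  "
            f"initial loss: {self.loss_history[0]:.4f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path, **{f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        )
        sidecar = {
            "config": asdict(self.config),
            "loss_history": self.loss_history,
            "train_spacing": list(self.train_spacing),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DetectionResults":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        raw = dict(sidecar["config"])
        for key in ("in_plane_patch", "hu_window"):
            raw[key] = tuple(raw[key])
        if raw.get("class_weights") is not None:
            raw["class_weights"] = tuple(raw["class_weights"])
        cfg = DetectionConfig(**raw)
        net = UNet(2, 1, cfg.n_classes, cfg.base_channels, cfg.depth,
                   np.random.default_rng(cfg.seed + 1))
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            net.load_state_arrays([z[f"p{i}"] for i in range(len(z.files))])
        return cls(net, cfg, sidecar["loss_history"], tuple(sidecar["train_spacing"]))
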