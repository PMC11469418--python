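"""Artifact transplantation: build paired training data with known truth.

A donor case contributes a segmented artifact (binary mask plus the
corrupted HU values under it); a recipient contributes an artifact-free
volume and a heart mask.  The donor artifact is translated so the two
heart centers of mass coincide (whole-voxel translation, no rotation or
scaling), gated to within a margin (default 3 voxels = 4.5 mm on the
1.5 mm working grid) of the recipient heart, and its corrupted HU values
are copied verbatim into the recipient.  The untouched recipient volume
is the ground truth, so every synthetic case is exactly paired.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BinaryMask, CTVolume, PhantomCase, center_of_mass, dilate
from .phantom import load_manifest, save_case

log = logging.getLogger(__name__)


@dataclass
class TransplantResult:
    """A synthetic paired case produced by artifact transplantation."""

    synthetic: CTVolume
    placed_mask: BinaryMask
    translation_vox: tuple[int, int, int]
    ground_truth: CTVolume
    usable: bool = True

    def as_case(self, recipient: PhantomCase) -> PhantomCase:
        """View as a PhantomCase sharing the recipient's anatomy masks."""
        return PhantomCase(
            clean=self.ground_truth,
            corrupted=self.synthetic,
            artifact_mask=self.placed_mask,
            heart_mask=recipient.heart_mask,
            chamber_masks=recipient.chamber_masks,
            seed=recipient.seed,
        )


def heart_alignment(donor_heart: BinaryMask, recipient_heart: BinaryMask) -> np.ndarray:
    """Whole-voxel translation taking the donor heart center to the recipient's.

    Both masks must live on the common working spacing; the translation is
    ``round((COM_recipient - COM_donor) / spacing)`` in voxels.
    """
    if not np.allclose(donor_heart.spacing, recipient_heart.spacing):
        raise ValueError("donor and recipient must share the working spacing")
    delta_mm = center_of_mass(recipient_heart) - center_of_mass(donor_heart)
    return np.round(delta_mm / np.asarray(donor_heart.spacing)).astype(int)


def _shift(arr: np.ndarray, t: np.ndarray, fill) -> np.ndarray:
    """Translate by whole voxels; content shifted off-grid is dropped."""
    out = np.full_like(arr, fill)
    src = [slice(max(0, -ti), arr.shape[i] - max(0, ti)) for i, ti in enumerate(t)]
    dst = [slice(max(0, ti), arr.shape[i] + min(0, ti)) for i, ti in enumerate(t)]
    if all(s.stop > s.start for s in src):
        out[tuple(dst)] = arr[tuple(src)]
    return out


def gate_mask(
    shifted_artifact: BinaryMask,
    recipient_heart: BinaryMask,
    margin_vox: int = 3,
) -> BinaryMask:
    """Keep only artifact voxels within ``margin_vox`` of the heart."""
    if shifted_artifact.shape != recipient_heart.shape:
        raise ValueError("masks must share a grid")
    gate = dilate(recipient_heart, margin_vox, element="euclidean")
    return BinaryMask.like(recipient_heart, shifted_artifact.voxels & gate.voxels)


def transplant(
    donor: PhantomCase,
    recipient_clean: CTVolume,
    recipient_heart: BinaryMask,
    margin_vox: int = 3,
) -> TransplantResult:
    """Place the donor artifact into an artifact-free recipient volume."""
    if donor.corrupted is None or donor.artifact_mask is None:
        raise ValueError("donor case carries no artifact")
    if donor.clean.shape != recipient_clean.shape:
        raise ValueError("donor and recipient must be on a common grid")

    t = heart_alignment(donor.heart_mask, recipient_heart)
    shifted_mask = BinaryMask.like(
        recipient_heart, _shift(donor.artifact_mask.voxels, t, False)
    )
    shifted_hu = _shift(donor.corrupted.voxels, t, 0.0)
    placed = gate_mask(shifted_mask, recipient_heart, margin_vox)

    synthetic = recipient_clean.voxels.copy()
    synthetic[placed.voxels] = shifted_hu[placed.voxels]

    usable = placed.voxels.any()
    if not usable:
        log.warning("gated artifact mask is empty; case unusable for training")
    dropped = donor.artifact_mask.count() - shifted_mask.count()
    if dropped:
        log.info("%d donor artifact voxels landed outside the recipient grid", dropped)

    return TransplantResult(
        synthetic=CTVolume(synthetic, recipient_clean.spacing, recipient_clean.origin),
        placed_mask=placed,
        translation_vox=tuple(int(v) for v in t),
        ground_truth=recipient_clean,
        usable=bool(usable),
    )


def build_training_set(
    donor_manifest: str | Path,
    recipient_manifest: str | Path,
    pairing_seed: int,
    out_dir: str | Path,
    margin_vox: int = 3,
    donors_per_recipient: int | None = None,
) -> Path:
    """Pair donors with recipients and write the transplanted cases.

    ``donors_per_recipient=None`` produces the all-pairs set; otherwise
    that many donors are drawn per recipient (without replacement when
    possible), deterministically from ``pairing_seed``.
    """
    donors = load_manifest(donor_manifest)
    recipients = load_manifest(recipient_manifest)
    if not donors or not recipients:
        raise ValueError("need at least one donor and one recipient")
    rng = np.random.default_rng(pairing_seed)

    pairs: list[tuple[int, int]] = []
    for ri in range(len(recipients)):
        if donors_per_recipient is None:
            pairs.extend((di, ri) for di in range(len(donors)))
        else:
            k = min(donors_per_recipient, len(donors))
            for di in rng.choice(len(donors), size=k, replace=False):
                pairs.append((int(di), ri))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (di, ri) in enumerate(pairs):
        rec = recipients[ri]
        res = transplant(donors[di], rec.clean, rec.heart_mask, margin_vox)
        case = res.as_case(rec)
        info = save_case(case, out / f"pair_{i:03d}")
        rows.append(
            {
                "case_id": f"pair_{i:03d}",
                "donor": di,
                "recipient": ri,
                "translation": json.dumps(list(res.translation_vox)),
                "usable": res.usable,
                **info,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
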