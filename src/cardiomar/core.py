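"""Core image containers, NIfTI I/O, resampling and binary morphology.

All volumes are axis-aligned 3D grids of Hounsfield units.  Arrays are
indexed ``(x, y, z)`` in RAS orientation (files are reoriented to the
closest canonical orientation on load), so axis 2 runs along the
scanner's z direction and an axial slice is ``voxels[:, :, k]``.
Physical coordinates are ``origin + index * spacing`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

# Standard 12-bit CT range; values outside are sentinel/overflow values.
HU_MIN = -1024.0
HU_MAX = 3071.0


class LoadError(ValueError):
    """Raised when a file cannot be interpreted as a 3D CT volume."""


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(np.asarray(x, dtype=float)))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class CTVolume:
    """A 3D scalar grid of HU values with voxel spacing and origin (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.voxels.ndim}D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing, self.origin)

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class BinaryMask:
    """A boolean grid aligned voxel-for-voxel with a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.voxels.ndim}D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @classmethod
    def like(cls, ref: "CTVolume | BinaryMask", voxels: np.ndarray) -> "BinaryMask":
        return cls(voxels, ref.spacing, ref.origin)

    @classmethod
    def empty_like(cls, ref: "CTVolume | BinaryMask") -> "BinaryMask":
        return cls(np.zeros(ref.shape, dtype=bool), ref.spacing, ref.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def count(self) -> int:
        return int(self.voxels.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.voxels.copy(), self.spacing, self.origin)

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class PhantomCase:
    """A paired training/evaluation unit: clean + corrupted volume and masks.

    ``clean`` and ``corrupted`` differ only inside ``artifact_mask``;
    chamber masks are pairwise disjoint subsets of ``heart_mask``.
    """

    clean: CTVolume
    heart_mask: BinaryMask
    chamber_masks: dict[int, BinaryMask]
    corrupted: CTVolume | None = None
    artifact_mask: BinaryMask | None = None
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def validate(self, margin_vox: int = 3) -> None:
        """Check pairing invariants; raises AssertionError on violation."""
        for m in self.chamber_masks.values():
            assert not np.any(m.voxels & ~self.heart_mask.voxels), "chamber outside heart"
        labels = sorted(self.chamber_masks)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert not np.any(
                    self.chamber_masks[a].voxels & self.chamber_masks[b].voxels
                ), f"chambers {a} and {b} overlap"
        if self.corrupted is not None and self.artifact_mask is not None:
            diff = self.clean.voxels != self.corrupted.voxels
            assert not np.any(diff & ~self.artifact_mask.voxels), (
                "corrupted differs from clean outside artifact mask"
            )
            gate = dilate(self.heart_mask, margin_vox)
            assert not np.any(self.artifact_mask.voxels & ~gate.voxels), (
                "artifact mask extends beyond the dilated heart"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_canonical(path: str):
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise LoadError(f"no such file: {path}") from None
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise LoadError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise LoadError(f"expected 3D volume, got shape {img.shape} in {path}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    return data, spacing, origin


def read_volume(path: str) -> CTVolume:
    """Read a NIfTI file as a CT volume (HU clamped to [-1024, 3071])."""
    data, spacing, origin = _load_canonical(path)
    if not np.all(np.isfinite(data)):
        raise LoadError(f"non-finite voxel values in {path}")
    data = np.clip(data, HU_MIN, HU_MAX)
    return CTVolume(data, spacing, origin)


def write_volume(vol: CTVolume, path: str) -> str:
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return str(path)


def read_mask(path: str) -> BinaryMask:
    """Read a NIfTI file as a binary mask (non-zero voxels are foreground)."""
    data, spacing, origin = _load_canonical(path)
    return BinaryMask(data > 0.5, spacing, origin)


def write_mask(mask: BinaryMask, path: str) -> str:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return str(path)


# ---------------------------------------------------------------------------
# Resampling


def resample_isotropic(obj, target_spacing_mm: float):
    """Resample a volume or mask to an isotropic grid.

    Linear interpolation for volumes, nearest-neighbour for masks.  A grid
    that is already at the target spacing is returned as an identical copy.
    """
    t = float(target_spacing_mm)
    if t <= 0:
        raise ValueError(f"target spacing must be positive, got {t}")
    if np.allclose(obj.spacing, (t, t, t)):
        return obj.copy()
    factors = [s / t for s in obj.spacing]
    if isinstance(obj, BinaryMask):
        out = ndimage.zoom(obj.voxels.astype(np.uint8), factors, order=0) > 0
        return BinaryMask(out, (t, t, t), obj.origin)
    out = ndimage.zoom(obj.voxels.astype(np.float32), factors, order=1)
    return CTVolume(out.astype(np.float32), (t, t, t), obj.origin)


# ---------------------------------------------------------------------------
# Morphology

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def dilate(mask: BinaryMask, radius_vox: int, element: str = "euclidean") -> BinaryMask:
    """Dilate a mask by ``radius_vox``.

    ``element='euclidean'`` sets every voxel whose Euclidean distance (in
    voxel units) to the mask is <= radius — the form used for margin gates
    and tolerances.  ``element='iterated'`` applies ``radius`` iterations
    of the full 3x3x3 neighbourhood.
    """
    r = int(radius_vox)
    if r < 0:
        raise ValueError("radius must be non-negative")
    if r == 0 or not mask.voxels.any():
        return mask.copy()
    if element == "euclidean":
        dist = ndimage.distance_transform_edt(~mask.voxels)
        return BinaryMask.like(mask, dist <= r + 1e-9)
    if element == "iterated":
        out = ndimage.binary_dilation(mask.voxels, structure=_STRUCT_26, iterations=r)
        return BinaryMask.like(mask, out)
    raise ValueError(f"unknown structuring element {element!r}")


def erode(mask: BinaryMask, radius_vox: int, element: str = "iterated") -> BinaryMask:
    """Erode a mask by ``radius_vox``.

    The default 'iterated' element peels ``radius`` full-neighbourhood
    (26-connected) shells, matching how an "N pixel" margin is eroded from
    a manual contour; 'euclidean' keeps voxels further than radius from
    the background.  Voxels outside the grid count as background.
    """
    r = int(radius_vox)
    if r < 0:
        raise ValueError("radius must be non-negative")
    if r == 0:
        return mask.copy()
    if element == "iterated":
        out = ndimage.binary_erosion(
            mask.voxels, structure=_STRUCT_26, iterations=r, border_value=0
        )
        return BinaryMask.like(mask, out)
    if element == "euclidean":
        dist = ndimage.distance_transform_edt(mask.voxels)
        return BinaryMask.like(mask, dist > r + 1e-9)
    raise ValueError(f"unknown structuring element {element!r}")


def surface_voxels(mask: BinaryMask) -> BinaryMask:
    """Voxels of the mask with at least one face-adjacent background voxel.

    The grid boundary counts as background, so a mask filling the whole
    grid has its outermost shell as surface.
    """
    if not mask.voxels.any():
        return mask.copy()
    interior = ndimage.binary_erosion(
        mask.voxels, structure=_STRUCT_6, border_value=0
    )
    return BinaryMask.like(mask, mask.voxels & ~interior)


def center_of_mass(mask: BinaryMask) -> np.ndarray:
    """Mean physical position (mm) of the set voxels."""
    if not mask.voxels.any():
        raise ValueError("center of mass of an empty mask is undefined")
    idx = np.argwhere(mask.voxels).mean(axis=0)
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)
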