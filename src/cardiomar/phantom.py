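"""Synthetic cardiac CT phantoms with paired streak-artifact corruption.

Each phantom emulates the anatomy a contrast cardiac CT shows around the
heart: soft-tissue background, two lung fields, an ellipsoidal heart with
a myocardial shell and four contrast-filled blood-pool chambers, and
rib-like bone arcs.  Artifacts mimic the streaks and shadows metal device
leads produce in reconstructed CT: bright and hypointense line segments
radiating in-plane from lead points inside the heart, spanning a few
adjacent slices, confined to a 3-voxel margin around the heart.

The generator provides paired (clean, corrupted) cases with ground-truth
masks, so detection and inpainting models can be trained and scored
without any acquired data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    BinaryMask,
    CTVolume,
    PhantomCase,
    dilate,
    read_mask,
    read_volume,
    write_mask,
    write_volume,
)


@dataclass
class PhantomSpec:
    """Geometry and HU palette of a synthetic cardiac volume.

    Defaults describe the working study conditions: a 64x64x32 grid at
    1.5 mm isotropic spacing with a contrast-enhanced blood pool
    (300 HU), myocardium at 100 HU, soft tissue at 40 HU, lung at
    -800 HU and cortical-bone arcs at 700 HU, plus 10 HU Gaussian noise.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: float = 1.5
    chamber_count: int = 4
    chamber_hu: float = 300.0
    myocardium_hu: float = 100.0
    tissue_hu: float = 40.0
    lung_hu: float = -800.0
    bone_hu: float = 700.0
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chamber_count < 1:
            raise ValueError("chamber_count must be >= 1")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if min(self.shape) < 16:
            raise ValueError("grid too small to contain a heart plus margin")


@dataclass
class ArtifactSpec:
    """Streak/shadow artifact layout.

    ``lead_points`` are voxel indices of metal-lead cross sections inside
    the heart; when empty, ``n_leads`` points are sampled from the blood
    pool.  Each lead carries a saturated cylindrical core of in-plane
    radius ``lead_core_radius_vox`` (the wire plus blooming) and
    emits ``n_streaks`` in-plane segments of width ``streak_width_vox``
    replicated over ``slice_span`` adjacent slices; a ``shadow_fraction``
    of streaks are hypointense.
    """

    lead_points: list[tuple[int, int, int]] = field(default_factory=list)
    n_leads: int = 2
    n_streaks: int = 6
    streak_width_vox: int = 2
    lead_core_radius_vox: float = 4.5
    slice_span: int = 5
    bright_hu: float = 600.0
    shadow_hu: float = 600.0
    shadow_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ValueError("shadow_fraction must lie in [0, 1]")
        if self.n_streaks < 0 or self.streak_width_vox < 1:
            raise ValueError("invalid streak geometry")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build a clean phantom (volume + heart and chamber masks).

    Deterministic given ``spec.seed``; geometry is jittered a little per
    seed so a dataset of phantoms is not a single repeated image.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    vol = np.full(spec.shape, spec.tissue_hu, dtype=np.float32)

    # Lung fields: lateral ellipsoids.
    for cx_frac in (0.17, 0.83):
        c = (
            cx_frac * nx + rng.uniform(-1, 1),
            0.5 * ny + rng.uniform(-2, 2),
            0.5 * nz,
        )
        ax = (0.16 * nx, 0.30 * ny, 0.55 * nz)
        vol[_ellipsoid(spec.shape, c, ax)] = spec.lung_hu

    # Heart: ellipsoid with myocardial shell and chamber blood pools.
    heart_c = np.array(
        [
            0.5 * nx + rng.uniform(-1.5, 1.5),
            0.47 * ny + rng.uniform(-1.5, 1.5),
            0.5 * nz + rng.uniform(-0.5, 0.5),
        ]
    )
    heart_ax = np.array([0.21 * nx, 0.23 * ny, 0.32 * nz])
    heart_ax *= rng.uniform(0.92, 1.08, size=3)
    heart = _ellipsoid(spec.shape, heart_c, heart_ax)
    lo = heart_c - heart_ax - 3.5
    hi = heart_c + heart_ax + 3.5
    if np.any(lo < 0) or np.any(hi > np.array(spec.shape)):
        raise ValueError("heart plus 3-voxel margin does not fit in the grid")
    vol[heart] = spec.myocardium_hu

    # Chambers: jittered ellipsoids in the four x-y quadrants of the
    # heart, kept pairwise separated by a one-voxel myocardial wall.
    quadrant_offsets = [(-1, -1), (1, -1), (-1, 1), (1, 1), (0, 0), (0, -1)]
    chambers: dict[int, BinaryMask] = {}
    inner = ndimage.binary_erosion(heart, np.ones((3, 3, 3), bool), iterations=2)
    occupied = np.zeros(spec.shape, dtype=bool)
    for k in range(spec.chamber_count):
        qx, qy = quadrant_offsets[k % len(quadrant_offsets)]
        c = (
            heart_c[0] + qx * 0.45 * heart_ax[0] + rng.uniform(-1, 1),
            heart_c[1] + qy * 0.45 * heart_ax[1] + rng.uniform(-1, 1),
            heart_c[2] + rng.uniform(-1, 1),
        )
        ax = (
            0.40 * heart_ax[0] * rng.uniform(0.85, 1.1),
            0.40 * heart_ax[1] * rng.uniform(0.85, 1.1),
            0.60 * heart_ax[2] * rng.uniform(0.85, 1.1),
        )
        pool = _ellipsoid(spec.shape, c, ax) & inner
        # septal walls ~3 voxels (4.5 mm), matching real myocardium
        wall = ndimage.binary_dilation(occupied, np.ones((3, 3, 3), bool), iterations=3)
        pool &= ~wall
        if not pool.any():
            raise ValueError(f"chamber {k} came out empty; enlarge the grid")
        occupied |= pool
        vol[pool] = spec.chamber_hu
        chambers[k + 1] = BinaryMask(pool, (spec.spacing_mm,) * 3)

    # Rib-like bone arcs: a thin cylindrical shell in x-y, interrupted
    # angularly and in z so it reads as ribs rather than a tube.
    gx, gy = np.ogrid[0:nx, 0:ny]
    r = np.sqrt(((gx - nx / 2) / 1.0) ** 2 + ((gy - ny / 2) * (nx / ny)) ** 2)
    ring = np.abs(r - 0.46 * nx) < 1.2
    theta = np.arctan2(gy - ny / 2, gx - nx / 2)
    arcs = ring & (np.cos(3.0 * theta + rng.uniform(0, np.pi)) > -0.2)
    bone = np.zeros(spec.shape, dtype=bool)
    z0 = int(rng.integers(0, 3))
    for z in range(z0, nz, 5):
        bone[:, :, z : z + 2] |= arcs[:, :, None]
    vol[bone] = spec.bone_hu

    if spec.noise_sd_hu > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    spacing = (spec.spacing_mm,) * 3
    return PhantomCase(
        clean=CTVolume(vol.astype(np.float32), spacing),
        heart_mask=BinaryMask(heart, spacing),
        chamber_masks=chambers,
        seed=spec.seed,
        meta={"bone_mask": bone},
    )


def _rasterize_streak(shape2d, start, angle, length) -> np.ndarray:
    """1-voxel-wide in-plane line segment from ``start`` along ``angle``."""
    n = int(np.ceil(length * 2))
    t = np.linspace(0.0, length, n)
    xs = np.clip(np.round(start[0] + t * np.cos(angle)).astype(int), 0, shape2d[0] - 1)
    ys = np.clip(np.round(start[1] + t * np.sin(angle)).astype(int), 0, shape2d[1] - 1)
    out = np.zeros(shape2d, dtype=bool)
    out[xs, ys] = True
    return out


def make_artifact(case: PhantomCase, aspec: ArtifactSpec) -> PhantomCase:
    """Corrupt a clean phantom with streak/shadow artifacts.

    The artifact mask is the union of in-plane streaks from each lead
    point, clipped to a 3-voxel Euclidean dilation of the heart (bright
    streaks win ties with shadows).  Outside the mask the corrupted
    volume equals the clean one exactly; inside, ``bright_hu`` is added
    or ``shadow_hu`` subtracted, so the pair stays exactly invertible.
    """
    rng = np.random.default_rng(aspec.seed)
    shape = case.clean.shape
    nx, ny, nz = shape
    heart = case.heart_mask

    leads = [tuple(int(v) for v in p) for p in aspec.lead_points]
    for p in leads:
        if not heart.voxels[p]:
            raise ValueError(f"lead point {p} lies outside the heart mask")
    if not leads:
        pool = np.zeros(shape, dtype=bool)
        for m in case.chamber_masks.values():
            pool |= m.voxels
        if pool.any():
            # a device lead runs along the chamber wall, not mid-cavity:
            # sample blood-pool voxels within 2 voxels of the wall
            near_wall = pool & (ndimage.distance_transform_edt(pool) <= 2.0)
            cand = np.argwhere(near_wall if near_wall.any() else pool)
        else:
            cand = np.argwhere(heart.voxels)
        # keep leads on mid slices so the slice span stays in-grid
        cand = cand[(cand[:, 2] >= nz // 4) & (cand[:, 2] <= 3 * nz // 4)]
        idx = rng.choice(len(cand), size=min(aspec.n_leads, len(cand)), replace=False)
        leads = [tuple(int(v) for v in cand[i]) for i in idx]

    bright2d = {}
    shadow2d = {}
    diag = float(np.hypot(nx, ny))
    for lead in leads:
        x0, y0, z0 = lead
        zs = range(
            max(0, z0 - aspec.slice_span // 2),
            min(nz, z0 + (aspec.slice_span + 1) // 2),
        )
        for _ in range(aspec.n_streaks):
            angle = rng.uniform(0, 2 * np.pi)
            is_shadow = rng.uniform() < aspec.shadow_fraction
            line = _rasterize_streak((nx, ny), (x0, y0), angle, diag)
            for z in zs:
                target = shadow2d if is_shadow else bright2d
                target[z] = target.get(z, np.zeros((nx, ny), bool)) | line

    bright = np.zeros(shape, dtype=bool)
    shadow = np.zeros(shape, dtype=bool)
    half = (aspec.streak_width_vox - 1 + 1) // 2
    disk = ndimage.generate_binary_structure(2, 2)
    for z, m in bright2d.items():
        bright[:, :, z] = ndimage.binary_dilation(m, disk, iterations=half) if half else m
    for z, m in shadow2d.items():
        shadow[:, :, z] = ndimage.binary_dilation(m, disk, iterations=half) if half else m

    if aspec.lead_core_radius_vox > 0:
        # the lead is a wire crossing axial slices: a bright cylinder
        gx, gy = np.ogrid[0:nx, 0:ny]
        half_z = aspec.slice_span // 2 + 2
        for x0, y0, z0 in leads:
            disk = (gx - x0) ** 2 + (gy - y0) ** 2 <= aspec.lead_core_radius_vox**2
            zlo, zhi = max(0, z0 - half_z), min(nz, z0 + half_z + 1)
            bright[:, :, zlo:zhi] |= disk[:, :, None]

    gate = dilate(heart, 3, element="euclidean").voxels
    bright &= gate
    shadow &= gate & ~bright  # bright takes precedence on overlap

    corrupted = case.clean.voxels.copy()
    corrupted[bright] += aspec.bright_hu
    corrupted[shadow] -= aspec.shadow_hu

    spacing = case.clean.spacing
    out = replace(
        case,
        corrupted=CTVolume(corrupted, spacing, case.clean.origin),
        artifact_mask=BinaryMask(bright | shadow, spacing, case.clean.origin),
    )
    out.meta = dict(case.meta, lead_points=leads)
    return out


def make_case(seed: int, spec: PhantomSpec | None = None,
              aspec: ArtifactSpec | None = None) -> PhantomCase:
    """Convenience: clean phantom + artifact corruption from one seed."""
    spec = replace(spec or PhantomSpec(), seed=seed)
    aspec = replace(aspec or ArtifactSpec(), seed=seed + 1)
    return make_artifact(make_phantom(spec), aspec)


# ---------------------------------------------------------------------------
# On-disk datasets

CASE_FILES = ("clean", "corrupted", "artifact_mask", "heart")


def save_case(case: PhantomCase, case_dir: str | Path) -> dict:
    d = Path(case_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(case.clean, d / "clean.nii.gz")
    if case.corrupted is not None:
        write_volume(case.corrupted, d / "corrupted.nii.gz")
    if case.artifact_mask is not None:
        write_mask(case.artifact_mask, d / "artifact_mask.nii.gz")
    write_mask(case.heart_mask, d / "heart.nii.gz")
    for k, m in case.chamber_masks.items():
        write_mask(m, d / f"chamber_{k}.nii.gz")
    return {"dir": str(d), "seed": case.seed, "n_chambers": len(case.chamber_masks)}


def load_case(case_dir: str | Path) -> PhantomCase:
    d = Path(case_dir)
    chambers = {}
    for f in sorted(d.glob("chamber_*.nii.gz")):
        k = int(f.name.split("_")[1].split(".")[0])
        chambers[k] = read_mask(f)
    corrupted_p = d / "corrupted.nii.gz"
    artifact_p = d / "artifact_mask.nii.gz"
    return PhantomCase(
        clean=read_volume(d / "clean.nii.gz"),
        corrupted=read_volume(corrupted_p) if corrupted_p.exists() else None,
        artifact_mask=read_mask(artifact_p) if artifact_p.exists() else None,
        heart_mask=read_mask(d / "heart.nii.gz"),
        chamber_masks=chambers,
    )


def make_dataset(
    n_cases: int,
    base_seed: int,
    out_dir: str | Path,
    spec: PhantomSpec | None = None,
    aspec: ArtifactSpec | None = None,
) -> Path:
    """Write ``n_cases`` paired phantom cases plus a manifest CSV.

    Case ``i`` uses seed ``base_seed + 1000 * i`` so regeneration with
    the same base seed reproduces every volume.
    Returns the manifest path.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_cases):
        seed = base_seed + 1000 * i
        case = make_case(seed, spec, aspec)
        info = save_case(case, out / f"case_{i:03d}")
        rows.append({"case_id": f"case_{i:03d}", **info})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (out / "manifest.json").write_text(json.dumps(rows, indent=1))
    return manifest


def load_manifest(manifest: "str | Path | pd.DataFrame") -> list[PhantomCase]:
    """Load all cases listed in a manifest CSV (or a pre-filtered frame)."""
    df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
    return [load_case(row["dir"]) for _, row in df.iterrows()]
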