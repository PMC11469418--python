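"""Brute-force reference implementations of every metric.

These deliberately use the dumbest correct formulation — python-level
set logic and all-pairs distance matrices — so they share nothing with
the package's EDT/morphology-based implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_surface(mask: np.ndarray) -> np.ndarray:
    """6-neighbour surface voxels; outside the grid counts as background."""
    out = np.zeros_like(mask)
    for p in np.argwhere(mask):
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = p + d
            if np.any(q < 0) or np.any(q >= mask.shape) or not mask[tuple(q)]:
                out[tuple(p)] = True
                break
    return out


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _directed(sa: np.ndarray, sb: np.ndarray, spacing) -> np.ndarray:
    pa = np.argwhere(sa) * np.asarray(spacing)
    pb = np.argwhere(sb) * np.asarray(spacing)
    return cdist(pa, pb).min(axis=1)


def brute_surface_dice(a, b, tol_vox: float) -> float:
    if not a.any() and not b.any():
        return 1.0
    if not a.any() or not b.any():
        return 0.0
    sa, sb = brute_surface(a), brute_surface(b)
    da = _directed(sa, sb, (1, 1, 1))
    db = _directed(sb, sa, (1, 1, 1))
    tol = tol_vox + 1e-9
    return (int((da <= tol).sum()) + int((db <= tol).sum())) / (len(da) + len(db))


def brute_surface_distances(a, b, spacing) -> tuple[float, float, float]:
    sa, sb = brute_surface(a), brute_surface(b)
    pooled = np.concatenate([_directed(sa, sb, spacing), _directed(sb, sa, spacing)])
    return float(pooled.mean()), float(pooled.max()), float(np.percentile(pooled, 95))


def brute_erode_iterated(mask: np.ndarray, r: int) -> np.ndarray:
    """r iterations of: keep a voxel iff its full 3x3x3 neighbourhood is set."""
    m = mask.copy()
    for _ in range(r):
        out = np.zeros_like(m)
        for p in np.argwhere(m):
            x, y, z = p
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        q = (x + dx, y + dy, z + dz)
                        if (
                            min(q) < 0
                            or any(qi >= s for qi, s in zip(q, m.shape))
                            or not m[q]
                        ):
                            ok = False
            if ok:
                out[x, y, z] = True
        m = out
    return m


def brute_dilate_euclidean(mask: np.ndarray, r: float) -> np.ndarray:
    """Voxels within Euclidean distance r (voxels) of any set voxel."""
    if not mask.any():
        return mask.copy()
    pts = np.argwhere(mask)
    grid = np.argwhere(np.ones(mask.shape, bool))
    d = cdist(grid, pts).min(axis=1)
    return (d <= r + 1e-9).reshape(mask.shape)


def brute_tpr(pred, manual, r: int) -> float:
    core = brute_erode_iterated(manual, r)
    n = int(core.sum())
    return float("nan") if n == 0 else int((pred & core).sum()) / n


def brute_tnr(pred, manual, r: float) -> float:
    neg = ~brute_dilate_euclidean(manual, r)
    n = int(neg.sum())
    return float("nan") if n == 0 else int((neg & ~pred).sum()) / n


def random_blob(rng: np.random.Generator, shape, n_seeds=2, radius=4.0) -> np.ndarray:
    """A random union of balls plus salt, as a plausible test mask."""
    out = np.zeros(shape, bool)
    grid = np.argwhere(np.ones(shape, bool)).reshape(*shape, 3)
    for _ in range(n_seeds):
        c = rng.uniform(0, np.asarray(shape))
        r = rng.uniform(1.0, radius)
        out |= ((grid - c) ** 2).sum(axis=-1) <= r * r
    salt = rng.random(shape) < 0.01
    return out | salt
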