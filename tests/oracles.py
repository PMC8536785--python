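"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — exhaustive searches and explicit
loops — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.spatial.distance import cdist


def brute_edt_squared(fg: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive nearest-background squared distance (μm²), 0 on background."""
    fg = np.asarray(fg, bool)
    spacing = np.asarray(spacing, float)
    out = np.zeros(fg.shape, dtype=np.float64)
    fg_idx = np.argwhere(fg)
    bg_idx = np.argwhere(~fg)
    if fg_idx.size == 0:
        return out
    if bg_idx.size == 0:
        raise ValueError("no background voxel")
    d2 = cdist(fg_idx * spacing, bg_idx * spacing, "sqeuclidean").min(axis=1)
    out[tuple(fg_idx.T)] = d2
    return out


def _offsets(connectivity: int):
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)]
    if connectivity == 6:
        return [o for o in offs if sum(map(abs, o)) == 1]
    if connectivity == 18:
        return [o for o in offs if sum(map(abs, o)) <= 2]
    if connectivity == 26:
        return offs
    raise ValueError(connectivity)


def bfs_hysteresis(vol: np.ndarray, low: float, high: float, connectivity: int) -> np.ndarray:
    """Breadth-first flood fill from voxels ≥ high through voxels ≥ low."""
    vol = np.asarray(vol)
    offs = _offsets(connectivity)
    passable = vol >= low
    visited = np.zeros(vol.shape, dtype=bool)
    queue = deque(map(tuple, np.argwhere(vol >= high)))
    for p in queue:
        visited[p] = True
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offs:
            q = (z + dz, y + dy, x + dx)
            if any(c < 0 or c >= n for c, n in zip(q, vol.shape)):
                continue
            if passable[q] and not visited[q]:
                visited[q] = True
                queue.append(q)
    return visited


def naive_mean_filter_2d(img: np.ndarray, block: int) -> np.ndarray:
    """Double-loop block mean with edge replication."""
    img = np.asarray(img, dtype=np.float64)
    h = block // 2
    H, W = img.shape
    out = np.zeros_like(img)
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for di in range(-h, h + 1):
                for dj in range(-h, h + 1):
                    ii = min(max(i + di, 0), H - 1)
                    jj = min(max(j + dj, 0), W - 1)
                    acc += img[ii, jj]
            out[i, j] = acc / block**2
    return out


def brute_thickness(fg: np.ndarray, spacing, chunk: int = 2000) -> np.ndarray:
    """Exhaustive largest-inscribed-sphere thickness.

    τ(p) = 2·max{D(c) : c foreground, ‖p − c‖ ≤ D(c)}, with D from the
    brute-force distance transform.
    """
    fg = np.asarray(fg, bool)
    spacing = np.asarray(spacing, float)
    D2 = brute_edt_squared(fg, spacing)
    out = np.zeros(fg.shape, dtype=np.float64)
    fg_idx = np.argwhere(fg)
    if fg_idx.size == 0:
        return out
    phys = fg_idx * spacing
    # compare in the exact squared domain so boundary ties (‖p−c‖ = D(c))
    # are resolved identically to the definition
    r2 = D2[tuple(fg_idx.T)]
    best = np.zeros(len(fg_idx))
    for k in range(0, len(fg_idx), chunk):
        d2 = cdist(phys[k : k + chunk], phys, "sqeuclidean")
        covered = d2 <= r2[None, :]
        best[k : k + chunk] = np.where(covered, r2[None, :], 0.0).max(axis=1)
    out[tuple(fg_idx.T)] = 2.0 * np.sqrt(best)
    return out


def random_blob_mask(rng: np.random.Generator, shape, p_fg: float | None = None) -> np.ndarray:
    """Random mask with spatial structure: thresholded smoothed noise."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=1.5)
    if p_fg is None:
        p_fg = rng.uniform(0.2, 0.8)
    thr = np.quantile(field, 1 - p_fg)
    return field >= thr
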