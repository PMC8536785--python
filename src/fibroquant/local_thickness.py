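"""Exact Euclidean distance transform and local fiber thickness.

Fiber diameters are quantified voxelwise through the *local thickness*
(largest-inscribed-sphere) map in the Hildebrand–Rüegsegger sense:

    τ(p) = 2 · max{ D(c) : c foreground, ‖p − c‖ ≤ D(c) }

where D is the Euclidean distance from a foreground voxel center to the
nearest background voxel center, in physical units (μm), supporting
anisotropic voxels (z spacing ≠ xy spacing).

The distance transform is the exact separable algorithm of Saito–Toriwaki:
three one-dimensional passes, each replacing every line sample with

    D²_new(i) = min_j  D²(j) + ((i − j)·s_axis)²

i.e. the lower envelope of parabolas rooted at the previous pass's values.
Each pass is exact, hence the composition is the exact squared Euclidean
distance; there is no chamfer/approximation step anywhere.

The thickness map is computed by "sphere painting" from the *distance
ridge* — the foreground voxels whose inscribed sphere is not contained in a
neighboring voxel's inscribed sphere. The ridge is a provably sufficient
set of centers: sphere(q) ⊇ sphere(p) iff D(q) ≥ D(p) + ‖p − q‖, and since
containment chains strictly increase D they terminate at a kept center, so
painting from the ridge yields a result bit-identical to painting from
every foreground voxel (verified by test).
"""

from __future__ import annotations

import itertools

import numpy as np

from .geometry import AcquisitionGeometry
from .images import BinaryMask, DistanceMap, ThicknessMap

__all__ = [
    "UnboundedDistanceError",
    "squared_edt",
    "distance_ridge",
    "local_thickness_map",
]

# Strict slack (μm) required before a ridge candidate may be discarded.
# Guarantees the ridge stays a superset of the centers that can contribute
# to τ even in the presence of float rounding of D and ‖p − q‖.
_RIDGE_EPS_UM = 1e-9

# Cap on the temporary array used by one vectorized parabola pass (floats).
_PASS_CHUNK_FLOATS = 4_000_000


class UnboundedDistanceError(ValueError):
    """Raised when every voxel is foreground and the border is not
    background: the nearest-background distance is undefined."""


def _parabola_pass(d2: np.ndarray, axis: int, s: float) -> np.ndarray:
    """One exact 1D pass: per line, d2_new[i] = min_j d2[j] + ((i-j)*s)**2."""
    moved = np.moveaxis(d2, axis, -1)
    n = moved.shape[-1]
    flat = np.ascontiguousarray(moved.reshape(-1, n))
    idx = np.arange(n, dtype=np.float64)
    # penalty[i, j] = ((i - j) * s)^2
    penalty = ((idx[:, None] - idx[None, :]) * s) ** 2
    out = np.empty_like(flat)
    chunk = max(1, _PASS_CHUNK_FLOATS // (n * n))
    for k in range(0, flat.shape[0], chunk):
        block = flat[k : k + chunk]  # (c, n) values at source index j
        out[k : k + chunk] = (block[:, None, :] + penalty[None, :, :]).min(axis=2)
    return np.moveaxis(out.reshape(moved.shape), -1, axis)


def _edt_squared(
    fg: np.ndarray,
    spacing: tuple[float, float, float],
    border_background: bool = False,
) -> np.ndarray:
    """Exact squared EDT (μm²) of a boolean foreground array."""
    fg = np.asarray(fg, dtype=bool)
    if border_background:
        padded = np.pad(fg, 1, constant_values=False)
        full = _edt_squared(padded, spacing, border_background=False)
        return full[1:-1, 1:-1, 1:-1]
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.float64)
    if fg.all():
        raise UnboundedDistanceError(
            "mask is entirely foreground and the border is not background; "
            "the distance transform is unbounded (set border_background=True "
            "to treat the outside of the volume as background)"
        )
    d2 = np.where(fg, np.inf, 0.0)
    for axis, s in enumerate(spacing):
        d2 = _parabola_pass(d2, axis, s)
    return d2


def squared_edt(mask: BinaryMask, border_background: bool = False) -> DistanceMap:
    """Anisotropy-aware exact Euclidean distance transform.

    Distances are center-to-center between voxel centers, scaled by
    ``(z_step, pixel_size_xy, pixel_size_xy)``. By default voxels outside
    the field of view are *not* background, so structures truncated by the
    FOV are not artificially thinned at the border; pass
    ``border_background=True`` to treat the outside as background.

    Raises
    ------
    UnboundedDistanceError
        If the mask has no background voxel and the border is foreground.
    """
    d2 = _edt_squared(mask.voxels, mask.geometry.spacing, border_background)
    return DistanceMap(values=np.sqrt(d2), squared=d2, geometry=mask.geometry)


def _neighbor_offsets(spacing: tuple[float, float, float]):
    """26-neighborhood offsets with their physical step lengths (μm)."""
    out = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        step = float(np.sqrt(sum((o * s) ** 2 for o, s in zip(off, spacing))))
        out.append((off, step))
    return out


def _shift_slices(off: tuple[int, int, int], shape: tuple[int, int, int]):
    """Slice pairs (dst, src) aligning voxel p (dst) with p+off (src)."""
    dst, src = [], []
    for o, n in zip(off, shape):
        if o == 0:
            dst.append(slice(0, n))
            src.append(slice(0, n))
        elif o > 0:
            dst.append(slice(0, n - o))
            src.append(slice(o, n))
        else:
            dst.append(slice(-o, n))
            src.append(slice(0, n + o))
    return tuple(dst), tuple(src)


def distance_ridge(dist: DistanceMap) -> np.ndarray:
    """Locally maximal inscribed-sphere centers.

    A foreground voxel p is dropped only if some 26-neighbor q satisfies
    D(q) ≥ D(p) + ‖p − q‖ + ε (its sphere strictly contains p's sphere),
    so the result is a superset of the centers needed to reconstruct the
    full thickness map.

    Returns an ``(N, 3)`` integer index array (z, y, x).
    """
    D = dist.values
    fg = D > 0
    dominated = np.zeros(D.shape, dtype=bool)
    for off, step in _neighbor_offsets(dist.geometry.spacing):
        dst, src = _shift_slices(off, D.shape)
        dominated[dst] |= (
            fg[dst] & fg[src] & (D[src] >= D[dst] + step + _RIDGE_EPS_UM)
        )
    return np.argwhere(fg & ~dominated)


def _paint_spheres(
    centers: np.ndarray,
    dist: DistanceMap,
) -> np.ndarray:
    """τ = 2·max D(c) over centers whose inscribed sphere covers each voxel."""
    D = dist.values
    D2 = dist.squared
    sz, sy, sx = dist.geometry.spacing
    nz, ny, nx = D.shape
    tau = np.zeros(D.shape, dtype=np.float64)
    if centers.size == 0:
        return tau
    # Descending radius: big spheres first so later (smaller) spheres skip
    # nothing but also cannot lower already-painted values (np.maximum).
    order = np.argsort(-D[tuple(centers.T)], kind="stable")
    ax_z = np.arange(nz, dtype=np.float64)
    ax_y = np.arange(ny, dtype=np.float64)
    ax_x = np.arange(nx, dtype=np.float64)
    for z, y, x in centers[order]:
        r = D[z, y, x]
        r2 = D2[z, y, x]
        t = 2.0 * r
        z0, z1 = max(0, z - int(r / sz) - 1), min(nz, z + int(r / sz) + 2)
        y0, y1 = max(0, y - int(r / sy) - 1), min(ny, y + int(r / sy) + 2)
        x0, x1 = max(0, x - int(r / sx) - 1), min(nx, x + int(r / sx) + 2)
        dz2 = ((ax_z[z0:z1] - z) * sz) ** 2
        dy2 = ((ax_y[y0:y1] - y) * sy) ** 2
        dx2 = ((ax_x[x0:x1] - x) * sx) ** 2
        d2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        region = tau[z0:z1, y0:y1, x0:x1]
        np.maximum(region, np.where(d2 <= r2, t, 0.0), out=region)
    return tau


def local_thickness_map(
    mask: BinaryMask,
    mode: str = "3d",
    centers: str = "ridge",
    border_background: bool = False,
) -> ThicknessMap:
    """Local thickness map τ (μm) of a binary fiber mask.

    Parameters
    ----------
    mask
        Foreground = fiber voxels.
    mode
        ``"3d"`` (default): spheres live in the full anisotropic volume.
        ``"2d"``: each slice is processed independently with disks in the
        xy plane; the result is labeled with the mode used.
    centers
        ``"ridge"`` (default) paints inscribed spheres from the distance
        ridge; ``"all"`` paints from every foreground voxel. The two are
        equivalent; ``"all"`` exists as the exhaustive reference.
    border_background
        Passed to :func:`squared_edt`.
    """
    if centers not in ("ridge", "all"):
        raise ValueError(f"centers must be 'ridge' or 'all', got {centers!r}")
    if mode == "2d":
        geom = mask.geometry
        values = np.zeros(geom.shape, dtype=np.float64)
        for k in range(geom.shape[0]):
            sub_geom = AcquisitionGeometry(
                pixel_size_xy=geom.pixel_size_xy,
                z_step=geom.z_step,
                shape=(1, geom.shape[1], geom.shape[2]),
            )
            sub = BinaryMask(mask.voxels[k : k + 1], sub_geom)
            values[k] = _thickness_3d(sub, centers, border_background)[0]
        return ThicknessMap(values=values, geometry=geom, mode="2d")
    if mode != "3d":
        raise ValueError(f"mode must be '3d' or '2d', got {mode!r}")
    values = _thickness_3d(mask, centers, border_background)
    return ThicknessMap(values=values, geometry=mask.geometry, mode="3d")


def _thickness_3d(mask: BinaryMask, centers: str, border_background: bool) -> np.ndarray:
    fg = mask.voxels
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.float64)
    dist = squared_edt(mask, border_background=border_background)
    if centers == "ridge":
        pts = distance_ridge(dist)
    else:
        pts = np.argwhere(fg)
    tau = _paint_spheres(pts, dist)
    # τ is defined on the foreground only; a background voxel lying exactly
    # on a sphere boundary must not be counted as fiber.
    tau[~fg] = 0.0
    return tau
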