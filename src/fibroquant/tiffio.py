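"""Multi-page TIFF reading/writing with physical geometry handling.

Config-supplied pixel sizes always win over TIFF metadata; a warning is
logged when the two disagree.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .geometry import AcquisitionGeometry
from .images import BinaryMask, ThicknessMap, VolumeImage

logger = logging.getLogger("fibroquant")

__all__ = ["read_stack", "write_stack", "read_mask", "write_mask", "write_thickness", "save_phantom"]


def _geometry_from_tags(tif: tifffile.TiffFile) -> tuple[Optional[float], Optional[float]]:
    """(pixel_size_xy, z_step) in μm from ImageJ metadata, when present."""
    px = zs = None
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                px = den / num  # resolution stored as pixels per unit
        meta = tif.imagej_metadata or {}
        if "spacing" in meta:
            zs = float(meta["spacing"])
    except Exception:  # noqa: BLE001 - metadata is best-effort
        pass
    return px, zs


def read_stack(
    path: str | Path,
    pixel_size_xy: Optional[float] = None,
    z_step: Optional[float] = None,
    channel_label: str = "",
) -> VolumeImage:
    """Read a multi-page TIFF as a :class:`VolumeImage`.

    Geometry comes from the arguments; TIFF/ImageJ tags are used only for
    values not supplied, and a conflict logs a warning (config wins).
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        tag_px, tag_zs = _geometry_from_tags(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D image or 3D stack, got shape {arr.shape}")
    for name, given, tagged in (("pixel_size_xy", pixel_size_xy, tag_px), ("z_step", z_step, tag_zs)):
        if given is not None and tagged is not None and not np.isclose(given, tagged, rtol=1e-3):
            logger.warning(
                "%s: configured %s=%g μm overrides TIFF metadata value %g μm",
                path, name, given, tagged,
            )
    px = pixel_size_xy if pixel_size_xy is not None else tag_px
    zs = z_step if z_step is not None else tag_zs
    if px is None or zs is None:
        raise ValueError(
            f"{path}: pixel_size_xy / z_step not given and not recoverable from TIFF tags"
        )
    geometry = AcquisitionGeometry(pixel_size_xy=px, z_step=zs, shape=arr.shape)
    return VolumeImage(np.asarray(arr, dtype=np.float64), geometry, channel_label)


def write_stack(path: str | Path, image: VolumeImage, dtype=np.float32) -> None:
    """Write a stack as a multi-page TIFF with ImageJ-style geometry tags."""
    geom = image.geometry
    tifffile.imwrite(
        str(path),
        np.asarray(image.voxels, dtype=dtype),
        imagej=True,
        resolution=(1.0 / geom.pixel_size_xy, 1.0 / geom.pixel_size_xy),
        metadata={"spacing": geom.z_step, "unit": "um", "axes": "ZYX"},
    )


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    img = VolumeImage(mask.voxels.astype(np.float64), mask.geometry)
    write_stack(path, img, dtype=np.uint8)


def read_mask(
    path: str | Path,
    pixel_size_xy: Optional[float] = None,
    z_step: Optional[float] = None,
) -> BinaryMask:
    img = read_stack(path, pixel_size_xy, z_step)
    return BinaryMask(img.voxels > 0, img.geometry, {"source": str(path)})


def write_thickness(path: str | Path, tau: ThicknessMap) -> None:
    """Thickness maps are written as 32-bit float μm stacks."""
    img = VolumeImage(tau.values, tau.geometry)
    write_stack(path, img, dtype=np.float32)


def save_phantom(out_dir: str | Path, image: VolumeImage, truth) -> None:
    """Write a phantom stack, its truth mask, and a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(out / "stack.tif", image)
    write_mask(out / "truth_mask.tif", truth.truth_mask)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, default=float)
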