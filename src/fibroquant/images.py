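"""In-memory containers shared by the pipeline stages.

Every container couples a numpy array with its :class:`AcquisitionGeometry`
so that all downstream measurements (distances, thicknesses, volumes) come
out in physical units (μm) rather than voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import AcquisitionGeometry


def _check_shape(arr: np.ndarray, geometry: AcquisitionGeometry, name: str) -> None:
    if arr.ndim != 3 or arr.shape != geometry.shape:
        raise ValueError(
            f"{name} array shape {arr.shape} does not match geometry shape {geometry.shape}"
        )


def check_same_geometry(a: "AcquisitionGeometry", b: "AcquisitionGeometry") -> None:
    if a != b:
        raise ValueError(f"geometry mismatch: {a} vs {b}")


@dataclass
class VolumeImage:
    """A 3D scalar intensity stack (one channel) with physical geometry."""

    voxels: np.ndarray
    geometry: AcquisitionGeometry
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        _check_shape(self.voxels, self.geometry, "VolumeImage")
        if not np.isfinite(self.voxels).all():
            raise ValueError("VolumeImage intensities must be finite")
        if self.voxels.min() < 0:
            raise ValueError("VolumeImage intensities must be non-negative")


@dataclass
class BinaryMask:
    """3D boolean foreground volume (collagen / channel-positive voxels).

    ``provenance`` records the parameters that produced the mask so results
    carry their own audit trail.
    """

    voxels: np.ndarray
    geometry: AcquisitionGeometry
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            raise ValueError(f"BinaryMask voxels must be boolean, got dtype {self.voxels.dtype}")
        _check_shape(self.voxels, self.geometry, "BinaryMask")

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_um3(self) -> float:
        return self.n_foreground * self.geometry.voxel_volume_um3


@dataclass
class DistanceMap:
    """Euclidean distance (μm) from each foreground voxel center to the
    nearest background voxel center; exactly 0 on background.

    ``squared`` holds the exact squared distances (μm²) from which ``values``
    is derived; comparisons against analytic oracles are done on ``squared``
    to avoid the extra square-root rounding.
    """

    values: np.ndarray
    squared: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        _check_shape(self.values, self.geometry, "DistanceMap")
        _check_shape(self.squared, self.geometry, "DistanceMap.squared")


@dataclass
class ThicknessMap:
    """Local thickness τ in μm: τ(p) is the diameter of the largest sphere
    fully contained in the foreground that covers p; 0 outside foreground.

    ``mode`` records whether the map was computed on the full stack ("3d")
    or slice by slice ("2d").
    """

    values: np.ndarray
    geometry: AcquisitionGeometry
    mode: str = "3d"

    def __post_init__(self) -> None:
        _check_shape(self.values, self.geometry, "ThicknessMap")
        if self.mode not in ("3d", "2d"):
            raise ValueError(f"mode must be '3d' or '2d', got {self.mode!r}")

    @property
    def foreground(self) -> np.ndarray:
        return self.values > 0
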