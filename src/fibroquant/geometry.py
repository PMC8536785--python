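"""Physical acquisition geometry of a 3D microscopy stack."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel geometry of a z-stack, in physical units.

    Parameters
    ----------
    pixel_size_xy
        In-plane sampling, μm per pixel. Typical SHG acquisitions here are
        ~0.073–0.1 μm per pixel.
    z_step
        Axial spacing between slices, μm.
    shape
        ``(n_slices, n_rows, n_cols)`` — the numpy axis order used for every
        array in this package (z, y, x).
    """

    pixel_size_xy: float
    z_step: float
    shape: tuple[int, int, int] = field()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pixel_size_xy) and self.pixel_size_xy > 0):
            raise ValueError(f"pixel_size_xy must be a positive finite μm value, got {self.pixel_size_xy}")
        if not (math.isfinite(self.z_step) and self.z_step > 0):
            raise ValueError(f"z_step must be a positive finite μm value, got {self.z_step}")
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers (n_slices, n_rows, n_cols), got {self.shape!r}")
        object.__setattr__(self, "shape", shape)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing per array axis ``(z, y, x)`` in μm."""
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume along (z, y, x) in μm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume_um3(self) -> float:
        return self.z_step * self.pixel_size_xy**2

    @property
    def voxel_diagonal_um(self) -> float:
        """Length of the main diagonal of one voxel, μm.

        The natural discretization tolerance: a continuous surface can fall
        anywhere inside a voxel, so digital distance/thickness estimates are
        only meaningful to within this length.
        """
        return math.sqrt(self.z_step**2 + 2 * self.pixel_size_xy**2)

    @property
    def n_voxels(self) -> int:
        return self.shape[0] * self.shape[1] * self.shape[2]

    def to_dict(self) -> dict:
        return {
            "pixel_size_xy": self.pixel_size_xy,
            "z_step": self.z_step,
            "shape": list(self.shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            pixel_size_xy=float(d["pixel_size_xy"]),
            z_step=float(d["z_step"]),
            shape=tuple(d["shape"]),
        )
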