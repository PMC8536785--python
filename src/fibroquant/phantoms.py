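"""Synthetic 3D fiber phantoms with known ground truth.

The study's raw SHG microscopy is not deposited, so validation rests on
phantoms: stacks of tubular "collagen fibers" with exactly known geometry.
A fiber is a constant-radius tube around a polyline centerline (a gentle
random walk), voxelized by the unambiguous rule *a voxel is foreground iff
its center lies within the fiber radius of the centerline* (point-to-
segment distance in physical μm). That rule gives an analytic volume
(πr²L) to compare voxel counts against, and a known diameter to compare
local-thickness output against.

Two regimes parameterize the biology: sparse thin fibers (diameter
< 1.5 μm, the healthy-control appearance) and confluent networks including
thick bundles (diameter ≥ 6 μm, the fibrotic appearance). The intensity
model is deliberately simple — constant fiber intensity, Gaussian PSF blur,
optional Poisson photon noise plus additive Gaussian read noise on a flat
background; no attempt is made to simulate SHG physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry
from .images import BinaryMask, VolumeImage, check_same_geometry
from .local_thickness import local_thickness_map

__all__ = [
    "NoiseModel",
    "DiameterDistribution",
    "control_like_spec",
    "disease_like_spec",
    "FiberPrimitive",
    "PhantomSpec",
    "PhantomTruth",
    "TwoChannelPhantom",
    "PhantomTargetError",
    "generate_fiber_phantom",
    "make_two_channel_phantom",
    "make_organoid_support",
]


class PhantomTargetError(RuntimeError):
    """Target volume fraction unachievable within the iteration cap."""

    def __init__(self, target_pct: float, achieved_pct: float, attempts: int):
        self.target_pct = target_pct
        self.achieved_pct = achieved_pct
        self.attempts = attempts
        super().__init__(
            f"could not reach target volume fraction {target_pct:.3f}% "
            f"(achieved {achieved_pct:.3f}% after {attempts} attempts)"
        )


@dataclass(frozen=True)
class NoiseModel:
    """Additive intensity corruption applied after PSF blurring.

    gaussian_sd: SD of additive Gaussian (read) noise, intensity units.
    poisson_scale: photons per intensity unit for shot noise; 0 disables.
    background_level: flat background added to every voxel.
    """

    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_scale < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class DiameterDistribution:
    """Named distribution of fiber diameters (μm).

    Construct via :meth:`fixed`, :meth:`uniform` or :meth:`mixture`.
    """

    kind: str
    params: tuple = ()
    components: tuple = ()  # mixture: ((weight, DiameterDistribution), ...)

    @classmethod
    def fixed(cls, diameter_um: float) -> "DiameterDistribution":
        if diameter_um <= 0:
            raise ValueError("diameter must be positive")
        return cls("fixed", (float(diameter_um),))

    @classmethod
    def uniform(cls, low_um: float, high_um: float) -> "DiameterDistribution":
        if not (0 < low_um <= high_um):
            raise ValueError("need 0 < low <= high")
        return cls("uniform", (float(low_um), float(high_um)))

    @classmethod
    def mixture(
        cls, components: Sequence[tuple[float, "DiameterDistribution"]]
    ) -> "DiameterDistribution":
        comps = tuple((float(w), d) for w, d in components)
        if not comps or any(w <= 0 for w, _ in comps):
            raise ValueError("mixture needs components with positive weights")
        return cls("mixture", (), comps)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.params[0]
        if self.kind == "uniform":
            return float(rng.uniform(*self.params))
        if self.kind == "mixture":
            weights = np.array([w for w, _ in self.components])
            i = rng.choice(len(self.components), p=weights / weights.sum())
            return self.components[i][1].sample(rng)
        raise ValueError(f"unknown diameter distribution kind {self.kind!r}")

    def to_dict(self) -> dict:
        if self.kind == "mixture":
            return {
                "kind": "mixture",
                "components": [
                    {"weight": w, "distribution": d.to_dict()} for w, d in self.components
                ],
            }
        return {"kind": self.kind, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "DiameterDistribution":
        kind = d["kind"]
        if kind == "fixed":
            return cls.fixed(d["params"][0])
        if kind == "uniform":
            return cls.uniform(*d["params"])
        if kind == "mixture":
            return cls.mixture(
                [(c["weight"], cls.from_dict(c["distribution"])) for c in d["components"]]
            )
        raise ValueError(f"unknown diameter distribution kind {kind!r}")


@dataclass(frozen=True)
class FiberPrimitive:
    """One tube: an ordered centerline of (z, y, x) points in μm with a
    constant radius and emission intensity."""

    centerline: tuple[tuple[float, float, float], ...]
    radius_um: float
    intensity: float = 100.0

    def __post_init__(self) -> None:
        pts = tuple(tuple(float(c) for c in p) for p in self.centerline)
        if len(pts) < 2:
            raise ValueError("centerline needs at least 2 points")
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise ValueError("consecutive centerline points must be distinct")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        object.__setattr__(self, "centerline", pts)

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    @property
    def length_um(self) -> float:
        pts = np.asarray(self.centerline)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def to_dict(self) -> dict:
        return {
            "centerline": [list(p) for p in self.centerline],
            "radius_um": self.radius_um,
            "intensity": self.intensity,
        }


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one phantom stack deterministically.

    Either give explicit ``fibers``, or a ``diameter_distribution`` with a
    fiber count (``n_fibers``) or a ``target_volume_fraction_pct`` that the
    generator iterates toward (tolerance ``target_tolerance_pp`` percentage
    points; failure past ``max_attempts`` raises
    :class:`PhantomTargetError` naming the achieved fraction).
    """

    geometry: AcquisitionGeometry
    n_fibers: int = 0
    diameter_distribution: Optional[DiameterDistribution] = None
    target_volume_fraction_pct: Optional[float] = None
    target_tolerance_pp: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    psf_sigma_um: float = 0.0
    fiber_intensity: float = 100.0
    fiber_length_um: Optional[float] = None
    step_um: float = 2.0
    bend_sd_rad: float = 0.25
    seed: int = 0
    fibers: Optional[tuple[FiberPrimitive, ...]] = None
    max_attempts: int = 2000

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        if self.target_volume_fraction_pct is not None and not (
            0 <= self.target_volume_fraction_pct <= 100
        ):
            raise ValueError("target_volume_fraction_pct must be in [0, 100]")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be non-negative")
        if self.target_tolerance_pp <= 0:
            raise ValueError("target_tolerance_pp must be positive")
        needs_dist = self.fibers is None and (
            self.n_fibers > 0
            or (self.target_volume_fraction_pct or 0) > self.target_tolerance_pp
        )
        if needs_dist and self.diameter_distribution is None:
            raise ValueError("diameter_distribution required to sample random fibers")
        if self.fibers is not None:
            object.__setattr__(self, "fibers", tuple(self.fibers))


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: the fiber primitives, the exact
    voxelized mask, per-voxel fiber labels (thickest fiber wins on
    overlap), and derived analytic statistics."""

    fibers: tuple[FiberPrimitive, ...]
    truth_mask: BinaryMask
    labels: np.ndarray  # int32; 0 = background, i+1 = fibers[i]

    @property
    def geometry(self) -> AcquisitionGeometry:
        return self.truth_mask.geometry

    @property
    def true_volume_fraction_pct(self) -> float:
        return 100.0 * self.truth_mask.n_foreground / self.geometry.n_voxels

    @cached_property
    def truth_thickness(self):
        """Local thickness map of the truth mask (computed on demand)."""
        return local_thickness_map(self.truth_mask)

    def true_thick_fraction_pct(self, threshold_um: float = 6.0) -> float:
        tau = self.truth_thickness.values
        return 100.0 * int((tau >= threshold_um).sum()) / self.geometry.n_voxels

    def fiber_voxels(self, i: int) -> np.ndarray:
        """Boolean mask of the voxels attributed to ``fibers[i]``."""
        return self.labels == i + 1

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "fibers": [f.to_dict() for f in self.fibers],
            "true_volume_fraction_pct": self.true_volume_fraction_pct,
        }


@dataclass
class TwoChannelPhantom:
    """Co-registered COL1A-like and CK8-like channels with their truths."""

    col_image: VolumeImage
    ck8_image: VolumeImage
    col_truth: PhantomTruth
    ck8_truth: PhantomTruth

    @property
    def true_volume_ratio(self) -> float:
        """Ground-truth fibrosis ratio: COL1A truth volume / CK8 truth
        volume (NaN when the CK8 truth is empty)."""
        ck8 = self.ck8_truth.truth_mask.volume_um3
        col = self.col_truth.truth_mask.volume_um3
        if ck8 == 0:
            return math.nan
        return col / ck8


def _voxelize_polyline(
    centerline: np.ndarray, radius_um: float, geometry: AcquisitionGeometry
) -> np.ndarray:
    """Voxels whose center lies within radius of the polyline (physical μm)."""
    spacing = np.asarray(geometry.spacing)
    shape = geometry.shape
    out = np.zeros(shape, dtype=bool)
    r2 = radius_um**2
    for a, b in zip(centerline[:-1], centerline[1:]):
        lo = np.minimum(a, b) - radius_um
        hi = np.maximum(a, b) + radius_um
        i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, shape)
        if (i0 >= i1).any():
            continue
        axes = [
            (np.arange(i0[k], i1[k], dtype=np.float64) * spacing[k]) - a[k]
            for k in range(3)
        ]
        pz = axes[0][:, None, None]
        py = axes[1][None, :, None]
        px = axes[2][None, None, :]
        ab = b - a
        len2 = float(ab @ ab)
        # t = clamp(((p-a)·ab)/|ab|², 0, 1); d² = |p-a - t·ab|²
        t = (pz * ab[0] + py * ab[1] + px * ab[2]) / len2
        np.clip(t, 0.0, 1.0, out=t)
        d2 = (pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (px - t * ab[2]) ** 2
        out[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= d2 <= r2
    return out


def _random_fiber(
    rng: np.random.Generator, spec: PhantomSpec, diameter_um: float
) -> FiberPrimitive:
    """Random-walk tube: uniform start, uniform initial direction, per-step
    Gaussian angular jitter of SD ``bend_sd_rad``."""
    extent = np.asarray(spec.geometry.extent_um)
    length = spec.fiber_length_um or 1.2 * float(extent.max())
    n_steps = max(1, int(round(length / spec.step_um)))
    start = rng.uniform(0, extent)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pts = [start]
    for _ in range(n_steps):
        direction = direction + rng.normal(scale=spec.bend_sd_rad, size=3)
        direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + direction * spec.step_um)
    return FiberPrimitive(
        centerline=tuple(tuple(p) for p in pts),
        radius_um=diameter_um / 2.0,
        intensity=spec.fiber_intensity,
    )


def _place_fibers(
    rng: np.random.Generator, spec: PhantomSpec
) -> tuple[list[FiberPrimitive], np.ndarray, np.ndarray]:
    """Build the fiber list, the union truth mask, and the label volume."""
    shape = spec.geometry.shape
    mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    radius_of_label = np.zeros(shape, dtype=np.float64)
    fibers: list[FiberPrimitive] = []

    def add(fiber: FiberPrimitive, vox: np.ndarray) -> None:
        fibers.append(fiber)
        np.logical_or(mask, vox, out=mask)
        claim = vox & (fiber.radius_um > radius_of_label)
        labels[claim] = len(fibers)
        radius_of_label[claim] = fiber.radius_um

    total = spec.geometry.n_voxels
    if spec.fibers is not None:
        for f in spec.fibers:
            add(f, _voxelize_polyline(np.asarray(f.centerline), f.radius_um, spec.geometry))
        return fibers, mask, labels

    if spec.target_volume_fraction_pct is not None:
        target = spec.target_volume_fraction_pct
        tol = spec.target_tolerance_pp
        attempts = 0
        while True:
            frac = 100.0 * mask.sum() / total
            if abs(frac - target) <= tol or frac > target:
                return fibers, mask, labels
            if attempts >= spec.max_attempts:
                raise PhantomTargetError(target, frac, attempts)
            attempts += 1
            d = spec.diameter_distribution.sample(rng)
            fiber = _random_fiber(rng, spec, d)
            vox = _voxelize_polyline(np.asarray(fiber.centerline), fiber.radius_um, spec.geometry)
            new_frac = 100.0 * (mask | vox).sum() / total
            if new_frac > target + tol:
                continue  # this fiber overshoots; try another
            add(fiber, vox)

    for _ in range(spec.n_fibers):
        d = spec.diameter_distribution.sample(rng)
        fiber = _random_fiber(rng, spec, d)
        add(fiber, _voxelize_polyline(np.asarray(fiber.centerline), fiber.radius_um, spec.geometry))
    return fibers, mask, labels


def generate_fiber_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PhantomTruth]:
    """Generate one synthetic SHG-like stack plus its ground truth.

    Identical ``spec`` (including ``seed``) produces bit-identical outputs:
    a single RNG stream seeded from ``spec.seed`` drives fiber placement
    and every noise draw, in a fixed order.
    """
    rng = np.random.default_rng(spec.seed)
    fibers, mask, labels = _place_fibers(rng, spec)

    img = np.zeros(spec.geometry.shape, dtype=np.float64)
    for i, f in enumerate(fibers):
        sel = labels == i + 1
        img[sel] = f.intensity
    # overlap voxels keep the label of the thickest fiber; make sure every
    # truth voxel emits at least the generic fiber intensity
    img[mask & (img == 0)] = spec.fiber_intensity

    if spec.psf_sigma_um > 0:
        sigma_vox = [spec.psf_sigma_um / s for s in spec.geometry.spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    img += spec.noise.background_level
    if spec.noise.poisson_scale > 0:
        img = rng.poisson(img * spec.noise.poisson_scale).astype(np.float64) / spec.noise.poisson_scale
    if spec.noise.gaussian_sd > 0:
        img = img + rng.normal(scale=spec.noise.gaussian_sd, size=img.shape)
    np.maximum(img, 0.0, out=img)

    truth = PhantomTruth(
        fibers=tuple(fibers),
        truth_mask=BinaryMask(mask, spec.geometry, {"operation": "phantom_truth", "seed": spec.seed}),
        labels=labels,
    )
    return VolumeImage(img, spec.geometry, channel_label="SHG-phantom"), truth


def make_two_channel_phantom(
    spec_col: PhantomSpec, spec_ck8: PhantomSpec
) -> TwoChannelPhantom:
    """Co-registered two-channel immunostain-like phantom (COL1A + CK8)."""
    check_same_geometry(spec_col.geometry, spec_ck8.geometry)
    col_img, col_truth = generate_fiber_phantom(spec_col)
    ck8_img, ck8_truth = generate_fiber_phantom(spec_ck8)
    col_img.channel_label = "COL1A-phantom"
    ck8_img.channel_label = "CK8-phantom"
    return TwoChannelPhantom(col_img, ck8_img, col_truth, ck8_truth)


_DEFAULT_NOISE = NoiseModel(gaussian_sd=5.0, poisson_scale=0.0, background_level=10.0)


def control_like_spec(
    geometry: AcquisitionGeometry,
    seed: int,
    noise: NoiseModel = _DEFAULT_NOISE,
    psf_sigma_um: float = 0.2,
) -> PhantomSpec:
    """Healthy-control regime: sparse thin fibers.

    Target collagen volume fraction 3% with fiber diameters drawn uniformly
    from 0.8–1.4 μm (all below the 1.5 μm "thin" bound); mild background,
    read noise and PSF blur. Fiber intensity is an arbitrary scale (100).
    """
    return PhantomSpec(
        geometry=geometry,
        diameter_distribution=DiameterDistribution.uniform(0.8, 1.4),
        target_volume_fraction_pct=3.0,
        noise=noise,
        psf_sigma_um=psf_sigma_um,
        seed=seed,
    )


def disease_like_spec(
    geometry: AcquisitionGeometry,
    seed: int,
    noise: NoiseModel = _DEFAULT_NOISE,
    psf_sigma_um: float = 0.2,
) -> PhantomSpec:
    """Fibrotic regime: confluent network including thick bundles.

    Target collagen volume fraction 17%, drawing 60% thin fibers
    (0.8–1.4 μm) and 40% thick bundles (6–8 μm diameter, at or above the
    6 μm "thick" threshold); same noise model as the control regime.
    """
    mix = DiameterDistribution.mixture(
        [
            (0.6, DiameterDistribution.uniform(0.8, 1.4)),
            (0.4, DiameterDistribution.uniform(6.0, 8.0)),
        ]
    )
    return PhantomSpec(
        geometry=geometry,
        diameter_distribution=mix,
        target_volume_fraction_pct=17.0,
        noise=noise,
        psf_sigma_um=psf_sigma_um,
        seed=seed,
    )


def make_organoid_support(
    geometry: AcquisitionGeometry,
    radius_um: float,
    center_um: Optional[tuple[float, float, float]] = None,
) -> BinaryMask:
    """Digital ball: voxels whose center lies within ``radius_um`` of
    ``center_um`` (defaults to the volume center), physical units.

    An infinite radius yields the full volume.
    """
    if not radius_um > 0:
        raise ValueError(f"radius_um must be positive, got {radius_um}")
    spacing = np.asarray(geometry.spacing)
    if center_um is None:
        center_um = tuple((n - 1) * s / 2.0 for n, s in zip(geometry.shape, spacing))
    if math.isinf(radius_um):
        return BinaryMask(np.ones(geometry.shape, dtype=bool), geometry,
                          {"operation": "organoid_support", "radius_um": radius_um})
    c = np.asarray(center_um, dtype=np.float64)
    axes = [
        (np.arange(geometry.shape[k], dtype=np.float64) * spacing[k] - c[k]) ** 2
        for k in range(3)
    ]
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    return BinaryMask(
        d2 <= radius_um**2,
        geometry,
        {"operation": "organoid_support", "radius_um": radius_um, "center_um": list(center_um)},
    )
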