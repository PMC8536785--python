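"""Turn masks and thickness maps into the reported fibrosis quantities.

Quantities computed here:

- **Collagen volume fraction** (%): binarized (collagen) voxels divided by
  all voxels of the stack.
- **Thick-fiber fraction** (%): voxels with local thickness ≥ 6 μm divided
  by *all* voxels of the stack — note the denominator is the total voxel
  count, not the collagen voxel count; this follows the quantification rule
  verbatim and changes values severalfold compared to a fiber-voxel
  denominator.
- **Periphery restriction**: analysis limited to the outer shell
  (< 50 μm by default) of the organoid body, to exclude possible
  hypoxia-induced signal from organoid cores.
- **Channel volume** (μm³) and the **fibrosis score**: ratio of segmented
  COL1A volume to CK8 volume over a whole-mount stack.
- **Area fraction** (%) of positive staining in 2D histology images, via a
  trainable per-pixel classifier (scribble-supervised, probability map,
  threshold, binarize).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier

from .images import BinaryMask, ThicknessMap, VolumeImage, check_same_geometry
from .local_thickness import squared_edt

__all__ = [
    "FiberQuantResult",
    "FibrosisScore",
    "AreaFractionResult",
    "PixelTrainingSet",
    "ProbabilityMap",
    "FeatureConfig",
    "PixelClassifier",
    "UndefinedScoreError",
    "volume_fraction",
    "thick_fraction",
    "quantify_stack",
    "restrict_to_periphery",
    "estimate_support",
    "channel_volume",
    "fibrosis_score",
    "train_pixel_classifier",
    "classify_pixels",
    "area_fraction",
]

DEFAULT_THICK_THRESHOLD_UM = 6.0
DEFAULT_PERIPHERY_DEPTH_UM = 50.0


class UndefinedScoreError(ZeroDivisionError):
    """Fibrosis score is undefined when the CK8 (denominator) volume is 0."""


@dataclass
class FiberQuantResult:
    """Per-stack collagen quantification with exact integer counts."""

    volume_fraction_pct: float
    thick_fraction_pct: float
    thick_threshold_um: float
    n_voxels_total: int
    n_voxels_collagen: int
    n_voxels_thick: int
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.thick_fraction_pct > self.volume_fraction_pct + 1e-12:
            raise ValueError("thick fraction cannot exceed volume fraction")


@dataclass
class FibrosisScore:
    col1a_volume_um3: float
    ck8_volume_um3: float
    score: float
    n_slices: int


@dataclass
class AreaFractionResult:
    area_fraction_pct: float
    n_pixels_positive: int
    n_pixels_total: int
    class_label: Any


@dataclass
class PixelTrainingSet:
    """A 2D image with sparse scribble labels (0 = unlabeled, k ≥ 1 =
    class k); needs at least two labeled classes."""

    image: np.ndarray  # (H, W) or (H, W, C)
    scribbles: np.ndarray  # (H, W) integer labels

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.scribbles = np.asarray(self.scribbles)
        if self.image.ndim == 2:
            self.image = self.image[:, :, None]
        if self.image.ndim != 3:
            raise ValueError("image must be (H, W) or (H, W, C)")
        if self.scribbles.shape != self.image.shape[:2]:
            raise ValueError("scribbles must match image height × width")
        classes = np.unique(self.scribbles)
        classes = classes[classes > 0]
        if classes.size < 2:
            raise ValueError("need scribbles for at least two classes")
        self.classes = tuple(int(c) for c in classes)


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities, (H, W, K); rows sum to 1."""

    values: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[2] != len(self.classes):
            raise ValueError("values must be (H, W, n_classes)")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(v.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")
        self.values = v

    def class_probability(self, class_label) -> np.ndarray:
        try:
            k = self.classes.index(class_label)
        except ValueError:
            raise KeyError(f"class {class_label!r} not in {self.classes}") from None
        return self.values[:, :, k]


# ---------------------------------------------------------------------------
# 3D stack quantities


def volume_fraction(mask: BinaryMask) -> FiberQuantResult:
    """Collagen volume fraction: 100 × collagen voxels / total voxels."""
    total = mask.geometry.n_voxels
    if total == 0:
        raise ValueError("empty geometry")
    n_col = mask.n_foreground
    return FiberQuantResult(
        volume_fraction_pct=100.0 * n_col / total,
        thick_fraction_pct=0.0,
        thick_threshold_um=math.inf,
        n_voxels_total=total,
        n_voxels_collagen=n_col,
        n_voxels_thick=0,
        params={"operation": "volume_fraction", **mask.provenance},
    )


def thick_fraction(
    tau: ThicknessMap, threshold_um: float = DEFAULT_THICK_THRESHOLD_UM
) -> FiberQuantResult:
    """Thick-fiber fraction: 100 × |{τ ≥ threshold}| / total stack voxels.

    The denominator is every voxel of the stack, not only fiber voxels.
    """
    if threshold_um < 0:
        raise ValueError("threshold_um must be >= 0")
    total = tau.geometry.n_voxels
    fg = tau.foreground
    n_col = int(fg.sum())
    # τ > 0 exactly on the fiber support, so threshold 0 counts it all
    n_thick = n_col if threshold_um == 0 else int((tau.values >= threshold_um).sum())
    return FiberQuantResult(
        volume_fraction_pct=100.0 * n_col / total,
        thick_fraction_pct=100.0 * n_thick / total,
        thick_threshold_um=threshold_um,
        n_voxels_total=total,
        n_voxels_collagen=n_col,
        n_voxels_thick=n_thick,
        params={"operation": "thick_fraction", "mode": tau.mode},
    )


def quantify_stack(
    mask: BinaryMask,
    tau: ThicknessMap,
    thick_threshold_um: float = DEFAULT_THICK_THRESHOLD_UM,
) -> FiberQuantResult:
    """Combined per-stack result from a mask and its thickness map."""
    check_same_geometry(mask.geometry, tau.geometry)
    vf = volume_fraction(mask)
    tf = thick_fraction(tau, thick_threshold_um)
    return FiberQuantResult(
        volume_fraction_pct=vf.volume_fraction_pct,
        thick_fraction_pct=tf.thick_fraction_pct,
        thick_threshold_um=thick_threshold_um,
        n_voxels_total=vf.n_voxels_total,
        n_voxels_collagen=vf.n_voxels_collagen,
        n_voxels_thick=tf.n_voxels_thick,
        params={**mask.provenance, "thickness_mode": tau.mode},
    )


def restrict_to_periphery(
    mask: BinaryMask,
    support: BinaryMask,
    depth_um: float = DEFAULT_PERIPHERY_DEPTH_UM,
    border_background: bool = False,
) -> BinaryMask:
    """Keep mask voxels lying in the outer shell of the organoid body.

    The shell is the set of support voxels whose Euclidean distance to the
    support's exterior is < ``depth_um`` (depth 0 keeps nothing).
    """
    check_same_geometry(mask.geometry, support.geometry)
    if not support.voxels.any():
        raise ValueError("support mask is empty")
    dist = squared_edt(support, border_background=border_background)
    shell = support.voxels & (dist.values < depth_um)
    return BinaryMask(
        mask.voxels & shell,
        mask.geometry,
        {**mask.provenance, "periphery_depth_um": depth_um},
    )


def estimate_support(
    img: VolumeImage,
    smooth_sigma_um: float = 2.0,
    closing_radius_um: float = 2.0,
) -> BinaryMask:
    """Heuristic organoid-body mask: Otsu threshold of the Gaussian-smoothed
    intensity, morphological closing, then hole filling.

    How the organoid body was delimited is an explicit design choice here;
    the parameters are recorded in the returned provenance.
    """
    sigma_vox = [smooth_sigma_um / s for s in img.geometry.spacing]
    smoothed = ndimage.gaussian_filter(img.voxels.astype(np.float64), sigma=sigma_vox)
    thr = float(threshold_otsu(smoothed))
    body = smoothed >= thr
    rad = [max(1, int(round(closing_radius_um / s))) for s in img.geometry.spacing]
    structure = np.ones((2 * rad[0] + 1, 2 * rad[1] + 1, 2 * rad[2] + 1), dtype=bool)
    body = ndimage.binary_closing(body, structure=structure)
    body = ndimage.binary_fill_holes(body)
    return BinaryMask(
        body,
        img.geometry,
        {
            "operation": "estimate_support",
            "smooth_sigma_um": smooth_sigma_um,
            "closing_radius_um": closing_radius_um,
            "otsu_threshold": thr,
        },
    )


def channel_volume(mask: BinaryMask) -> float:
    """Segmented channel volume in μm³: per-slice positive area summed over
    slices times the slice depth (= voxel count × voxel volume)."""
    geom = mask.geometry
    area_per_slice = mask.voxels.reshape(geom.shape[0], -1).sum(axis=1) * geom.pixel_size_xy**2
    return float(area_per_slice.sum() * geom.z_step)


def fibrosis_score(col_mask: BinaryMask, ck8_mask: BinaryMask) -> FibrosisScore:
    """Fibrosis score: segmented COL1A volume / CK8 volume over a stack.

    Raises :class:`UndefinedScoreError` if the CK8 volume is zero.
    """
    check_same_geometry(col_mask.geometry, ck8_mask.geometry)
    col_v = channel_volume(col_mask)
    ck8_v = channel_volume(ck8_mask)
    if ck8_v == 0:
        raise UndefinedScoreError("CK8 volume is zero; fibrosis score undefined")
    return FibrosisScore(
        col1a_volume_um3=col_v,
        ck8_volume_um3=ck8_v,
        score=col_v / ck8_v,
        n_slices=col_mask.geometry.shape[0],
    )


# ---------------------------------------------------------------------------
# Trainable pixel classification (area-fraction mode)


@dataclass(frozen=True)
class FeatureConfig:
    """Per-pixel feature stack: raw channels, Gaussian smoothings and
    Gaussian gradient magnitudes at each σ (pixels)."""

    sigmas_px: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    include_raw: bool = True

    def feature_names(self, n_channels: int) -> list[str]:
        names = []
        for c in range(n_channels):
            if self.include_raw:
                names.append(f"ch{c}/raw")
            for s in self.sigmas_px:
                names.append(f"ch{c}/gauss{s:g}")
                names.append(f"ch{c}/gradmag{s:g}")
        return names


@dataclass
class PixelClassifier:
    """A fitted per-pixel classifier plus everything needed to apply it."""

    model: RandomForestClassifier
    feature_config: FeatureConfig
    classes: tuple
    n_channels: int
    feature_names: list[str]


def _feature_stack(image: np.ndarray, config: FeatureConfig) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    feats = []
    for c in range(image.shape[2]):
        ch = image[:, :, c]
        if config.include_raw:
            feats.append(ch)
        for s in config.sigmas_px:
            feats.append(ndimage.gaussian_filter(ch, s, mode="nearest"))
            gy = ndimage.gaussian_filter(ch, s, order=(1, 0), mode="nearest")
            gx = ndimage.gaussian_filter(ch, s, order=(0, 1), mode="nearest")
            feats.append(np.hypot(gy, gx))
    return np.stack(feats, axis=-1)


def train_pixel_classifier(
    train: PixelTrainingSet,
    feature_config: Optional[FeatureConfig] = None,
    seed: int = 0,
    n_estimators: int = 100,
) -> PixelClassifier:
    """Fit a random-forest pixel classifier on scribble-labeled pixels.

    Deterministic for fixed inputs and ``seed``; the fitted feature list is
    recorded alongside the model.
    """
    config = feature_config or FeatureConfig()
    feats = _feature_stack(train.image, config)
    labeled = train.scribbles > 0
    X = feats[labeled]
    y = train.scribbles[labeled]
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return PixelClassifier(
        model=model,
        feature_config=config,
        classes=tuple(int(c) for c in model.classes_),
        n_channels=train.image.shape[2],
        feature_names=config.feature_names(train.image.shape[2]),
    )


def classify_pixels(clf: PixelClassifier, image: np.ndarray) -> ProbabilityMap:
    """Apply a trained classifier, producing a per-pixel probability map."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.shape[2] != clf.n_channels:
        raise ValueError(
            f"image has {image.shape[2]} channels; classifier trained on {clf.n_channels}"
        )
    feats = _feature_stack(image, clf.feature_config)
    h, w, f = feats.shape
    probs = clf.model.predict_proba(feats.reshape(-1, f)).reshape(h, w, -1)
    return ProbabilityMap(values=probs, classes=clf.classes)


def area_fraction(
    prob: ProbabilityMap, class_label, prob_threshold: float = 0.5
) -> AreaFractionResult:
    """Area fraction of one class: binarize P(class) ≥ threshold, then the
    exact positive-pixel fraction × 100."""
    p = prob.class_probability(class_label)
    positive = p >= prob_threshold
    n_pos = int(positive.sum())
    n_tot = int(p.size)
    return AreaFractionResult(
        area_fraction_pct=100.0 * n_pos / n_tot,
        n_pixels_positive=n_pos,
        n_pixels_total=n_tot,
        class_label=class_label,
    )
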