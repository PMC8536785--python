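"""Group statistics, run configuration, and the end-to-end pipeline.

Group differences are assessed with the two-tailed unpaired t-test
(pooled-variance Student's by default, Welch optional), reported with the
conventional star annotation (*p<0.05, **p<0.01, ***p<0.001) and no
multiple-testing correction — a choice stated in report footers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .geometry import AcquisitionGeometry
from .images import VolumeImage
from .phantoms import DiameterDistribution, NoiseModel, PhantomSpec, generate_fiber_phantom
from .quantify import (
    DEFAULT_PERIPHERY_DEPTH_UM,
    DEFAULT_THICK_THRESHOLD_UM,
    estimate_support,
    quantify_stack,
    restrict_to_periphery,
)
from .local_thickness import local_thickness_map
from .shg_segment import HysteresisParams, hysteresis_threshold, mean_filter_xy

__all__ = [
    "GroupComparison",
    "StackSource",
    "RunConfig",
    "significance_stars",
    "ttest_unpaired",
    "compare_groups",
    "run_pipeline",
]

logger = logging.getLogger("fibroquant")

REPORT_FOOTER = (
    "Two-tailed unpaired t-test; *p<0.05, **p<0.01, ***p<0.001. "
    "No multiple-testing correction applied."
)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    df: float
    p_two_tailed: float
    variant: str
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_two_tailed)


def ttest_unpaired(
    values_a,
    values_b,
    variant: str = "student_pooled",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-tailed unpaired t-test.

    ``variant='student_pooled'`` uses the pooled-variance Student statistic
    with df = n_a + n_b − 2; ``variant='welch'`` uses the Welch statistic
    with Satterthwaite df. Degenerate zero-variance inputs: equal means give
    t = 0, p = 1 by convention; unequal means give t = ±inf, p = 0, flagged
    ``degenerate=True``.
    """
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"variant must be 'student_pooled' or 'welch', got {variant!r}")
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    na, nb = a.size, b.size
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))

    if variant == "student_pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        denom = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        denom = math.sqrt(va / na + vb / nb)
        if denom > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2

    degenerate = False
    if denom == 0:
        if ma == mb:
            t = 0.0
            p = 1.0
        else:
            t = math.inf if ma > mb else -math.inf
            p = 0.0
            degenerate = True
    else:
        t = (ma - mb) / denom
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=na,
        n_b=nb,
        mean_a=ma,
        mean_b=mb,
        sd_a=math.sqrt(va),
        sd_b=math.sqrt(vb),
        t_statistic=t,
        df=float(df),
        p_two_tailed=p,
        variant=variant,
        degenerate=degenerate,
    )


def compare_groups(
    results: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    variant: str = "student_pooled",
) -> pd.DataFrame:
    """All pairwise group comparisons of one metric column."""
    groups = sorted(results[group_col].unique())
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            cmp_ = ttest_unpaired(
                results.loc[results[group_col] == ga, metric],
                results.loc[results[group_col] == gb, metric],
                variant=variant,
                group_a=str(ga),
                group_b=str(gb),
            )
            rows.append(
                {
                    "metric": metric,
                    "group_a": cmp_.group_a,
                    "group_b": cmp_.group_b,
                    "n_a": cmp_.n_a,
                    "n_b": cmp_.n_b,
                    "mean_a": cmp_.mean_a,
                    "mean_b": cmp_.mean_b,
                    "sd_a": cmp_.sd_a,
                    "sd_b": cmp_.sd_b,
                    "t_statistic": cmp_.t_statistic,
                    "df": cmp_.df,
                    "p_two_tailed": cmp_.p_two_tailed,
                    "significance": cmp_.stars,
                    "variant": cmp_.variant,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass
class StackSource:
    """One input stack: a TIFF path or an inline phantom specification."""

    stack_id: str
    group: str
    path: Optional[str] = None
    phantom: Optional[dict] = None
    unit_of_replication: str = "stack"

    def __post_init__(self) -> None:
        if (self.path is None) == (self.phantom is None):
            raise ValueError(f"stack {self.stack_id!r}: give exactly one of path/phantom")


@dataclass
class RunConfig:
    """Serializable configuration for an end-to-end run."""

    geometry: AcquisitionGeometry
    hysteresis: HysteresisParams
    inputs: list[StackSource]
    block_px: int = 5
    thickness_mode: str = "3d"
    thick_threshold_um: float = DEFAULT_THICK_THRESHOLD_UM
    periphery_enabled: bool = False
    periphery_depth_um: float = DEFAULT_PERIPHERY_DEPTH_UM
    seed: int = 0
    output_dir: Optional[str] = None
    ttest_variant: str = "student_pooled"

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "hysteresis": {
                "low": self.hysteresis.low,
                "high": self.hysteresis.high,
                "connectivity": self.hysteresis.connectivity,
                "threshold_mode": self.hysteresis.threshold_mode,
            },
            "block_px": self.block_px,
            "thickness_mode": self.thickness_mode,
            "thick_threshold_um": self.thick_threshold_um,
            "periphery": {
                "enabled": self.periphery_enabled,
                "depth_um": self.periphery_depth_um,
            },
            "seed": self.seed,
            "ttest_variant": self.ttest_variant,
            "inputs": [
                {
                    "stack_id": s.stack_id,
                    "group": s.group,
                    "path": s.path,
                    "phantom": s.phantom,
                    "unit_of_replication": s.unit_of_replication,
                }
                for s in self.inputs
            ],
            "output_dir": self.output_dir,
        }

    @property
    def config_hash(self) -> str:
        # output location is not semantic: two runs of the same analysis
        # into different directories must hash (and report) identically
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=float).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        hyst = d.get("hysteresis", {})
        per = d.get("periphery", {})
        return cls(
            geometry=AcquisitionGeometry.from_dict(d["geometry"]),
            hysteresis=HysteresisParams(
                low=float(hyst["low"]),
                high=float(hyst.get("high", float("nan"))),
                connectivity=int(hyst.get("connectivity", 26)),
                threshold_mode=hyst.get("threshold_mode", "absolute"),
            ),
            inputs=[
                StackSource(
                    stack_id=str(s["stack_id"]),
                    group=str(s["group"]),
                    path=s.get("path"),
                    phantom=s.get("phantom"),
                    unit_of_replication=s.get("unit_of_replication", "stack"),
                )
                for s in d["inputs"]
            ],
            block_px=int(d.get("block_px", 5)),
            thickness_mode=d.get("thickness_mode", "3d"),
            thick_threshold_um=float(d.get("thick_threshold_um", DEFAULT_THICK_THRESHOLD_UM)),
            periphery_enabled=bool(per.get("enabled", False)),
            periphery_depth_um=float(per.get("depth_um", DEFAULT_PERIPHERY_DEPTH_UM)),
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir"),
            ttest_variant=d.get("ttest_variant", "student_pooled"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def phantom_spec_from_dict(
    d: dict, geometry: AcquisitionGeometry, seed: int
) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from the inline config representation."""
    noise = d.get("noise", {})
    return PhantomSpec(
        geometry=geometry,
        n_fibers=int(d.get("n_fibers", 0)),
        diameter_distribution=(
            DiameterDistribution.from_dict(d["diameters"]) if "diameters" in d else None
        ),
        target_volume_fraction_pct=d.get("target_volume_fraction_pct"),
        target_tolerance_pp=float(d.get("target_tolerance_pp", 1.0)),
        noise=NoiseModel(
            gaussian_sd=float(noise.get("gaussian_sd", 0.0)),
            poisson_scale=float(noise.get("poisson_scale", 0.0)),
            background_level=float(noise.get("background_level", 0.0)),
        ),
        psf_sigma_um=float(d.get("psf_sigma_um", 0.0)),
        fiber_intensity=float(d.get("fiber_intensity", 100.0)),
        fiber_length_um=d.get("fiber_length_um"),
        seed=seed,
    )


def _load_stack(source: StackSource, config: RunConfig, index: int) -> VolumeImage:
    if source.path is not None:
        from .tiffio import read_stack

        return read_stack(
            source.path,
            pixel_size_xy=config.geometry.pixel_size_xy,
            z_step=config.geometry.z_step,
        )
    # Per-stack phantom seed derived deterministically from the run seed.
    seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
    stack_seed = int(seq.generate_state(1)[0] % (2**31))
    spec = phantom_spec_from_dict(source.phantom, config.geometry, stack_seed)
    img, _ = generate_fiber_phantom(spec)
    return img


def process_stack(img: VolumeImage, config: RunConfig) -> dict[str, Any]:
    """segment → (optional periphery restriction) → thickness → quantify."""
    filtered = mean_filter_xy(img, config.block_px)
    mask = hysteresis_threshold(filtered, config.hysteresis)
    if config.periphery_enabled:
        support = estimate_support(filtered)
        mask = restrict_to_periphery(mask, support, config.periphery_depth_um)
    tau = local_thickness_map(mask, mode=config.thickness_mode)
    res = quantify_stack(mask, tau, config.thick_threshold_um)
    return {
        "volume_fraction_pct": res.volume_fraction_pct,
        "thick_fraction_pct": res.thick_fraction_pct,
        "thick_threshold_um": res.thick_threshold_um,
        "n_voxels_total": res.n_voxels_total,
        "n_voxels_collagen": res.n_voxels_collagen,
        "n_voxels_thick": res.n_voxels_thick,
        "thickness_mode": tau.mode,
    }


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full pipeline over a manifest of stacks.

    Returns ``{"results": per-stack table, "comparisons": group t-tests}``
    and, when ``config.output_dir`` is set, writes ``results.csv``,
    ``comparisons.csv`` and a JSON provenance sidecar. Per-stack failures
    are isolated and logged; the run fails only if every stack fails.
    """
    rows = []
    failures = []
    for i, source in enumerate(config.inputs):
        try:
            img = _load_stack(source, config, i)
            row = process_stack(img, config)
        except Exception as exc:  # noqa: BLE001 - per-stack isolation
            logger.error("stack %s failed: %s", source.stack_id, exc)
            failures.append((source.stack_id, str(exc)))
            continue
        rows.append(
            {
                "stack_id": source.stack_id,
                "group": source.group,
                "unit_of_replication": source.unit_of_replication,
                **row,
                "config_hash": config.config_hash,
            }
        )
    if not rows:
        raise RuntimeError(f"all stacks failed: {failures}")
    results = pd.DataFrame(rows)

    comparisons = []
    if results["group"].nunique() >= 2:
        counts = results.groupby("group").size()
        if (counts >= 2).all():
            for metric in ("volume_fraction_pct", "thick_fraction_pct"):
                comparisons.append(
                    compare_groups(results, metric, variant=config.ttest_variant)
                )
    comparisons_df = (
        pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        comparisons_df.to_csv(out / "comparisons.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    "config": config.to_dict(),
                    "config_hash": config.config_hash,
                    "failures": failures,
                    "footer": REPORT_FOOTER,
                },
                fh,
                indent=2,
                default=float,
            )
    return {"results": results, "comparisons": comparisons_df}
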