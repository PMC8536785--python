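# fibroquant

Quantification of fibrillar collagen in 3D microscopy stacks, built for
studies of fibrotic disease in liver tissue and iPSC-derived hepatic
organoids — for example autosomal recessive polycystic kidney disease
(ARPKD), where congenital hepatic fibrosis produces a confluent network of
thick collagen bundles in place of the sparse sub-1.5 μm fibers of healthy
tissue. Second-harmonic-generation (SHG) microscopy images cross-linked
collagen label-free in 3D; `fibroquant` turns such stacks (and whole-mount
immunofluorescence stacks) into the standard fibrosis readouts.

## What it computes

For an SHG z-stack with voxel geometry (Δxy, Δz in μm):

1. **Segmentation** — slice-wise mean filtering (block 5 px) followed by
   two-threshold **hysteresis binarization**: voxels with intensity ≥ t_high
   are collagen; voxels with t_low ≤ v < t_high are collagen only if
   connected to a ≥ t_high voxel through voxels ≥ t_low.
2. **Collagen volume fraction** — CVF = 100 · |mask| / |stack| (%).
3. **Local thickness** — the exact anisotropic Euclidean distance transform
   D (separable Saito–Toriwaki parabola passes), then the
   largest-inscribed-sphere thickness map
   τ(p) = 2 · max{ D(c) : ‖p − c‖ ≤ D(c) }, computed efficiently from the
   distance ridge. τ(p) is the local fiber/bundle diameter in μm.
4. **Thick-fiber fraction** — TFF = 100 · |{τ ≥ 6 μm}| / |stack| (%). The
   denominator is the whole stack, not the fiber voxels.
5. **Periphery restriction** — optional limitation of the analysis to the
   outer < 50 μm shell of the organoid body (to exclude potentially hypoxic
   cores).
6. **Fibrosis score** — for two-channel whole-mount stacks, the ratio of
   segmented COL1A volume to CK8 volume, volumes computed as
   Σ(slice area) × Δz.
7. **Area fractions** in 2D histology via a scribble-trained random-forest
   pixel classifier (probability map → threshold → binarize → exact pixel
   fraction).
8. **Group statistics** — two-tailed unpaired t-tests (pooled Student's by
   default, Welch optional), with */**/*** annotation.

Because raw study imagery is rarely shareable, the package ships a
first-class **phantom generator**: tubular fibers with known centerlines,
radii and voxelized masks, in a "control-like" regime (3% CVF, diameters
0.8–1.4 μm) and a "disease-like" regime (17% CVF with 6–8 μm bundles), so
every stage can be validated against exact ground truth.

## Worked example

Ten phantoms — five control-like, five fibrotic — pushed through the full
pipeline (mean filter → hysteresis at 30/60 → local thickness → fractions
→ t-tests):

```python
from fibroquant import (
    AcquisitionGeometry, HysteresisParams, RunConfig, StackSource, run_pipeline,
)

geometry = AcquisitionGeometry(pixel_size_xy=0.5, z_step=0.5, shape=(20, 128, 128))
thin = {"target_volume_fraction_pct": 3.0,
        "diameters": {"kind": "uniform", "params": [0.8, 1.4]},
        "noise": {"gaussian_sd": 5.0, "background_level": 10.0}, "psf_sigma_um": 0.2}
fibrotic = {"target_volume_fraction_pct": 17.0,
            "diameters": {"kind": "mixture", "components": [
                {"weight": 0.6, "distribution": {"kind": "uniform", "params": [0.8, 1.4]}},
                {"weight": 0.4, "distribution": {"kind": "uniform", "params": [6.0, 8.0]}}]},
            "noise": {"gaussian_sd": 5.0, "background_level": 10.0}, "psf_sigma_um": 0.2}

config = RunConfig(
    geometry=geometry,
    hysteresis=HysteresisParams(low=30.0, high=60.0),
    inputs=[StackSource(f"control_{i}", "control", phantom=thin) for i in range(5)]
         + [StackSource(f"arpkd_{i}", "arpkd", phantom=fibrotic) for i in range(5)],
    seed=42,
)
out = run_pipeline(config)
print(out["results"][["stack_id", "group", "volume_fraction_pct", "thick_fraction_pct"]]
      .round(3).to_string(index=False))
print(out["comparisons"][["metric", "mean_a", "mean_b", "t_statistic", "p_two_tailed", "significance"]]
      .round(4).to_string(index=False))
```

Output:

```
 stack_id   group  volume_fraction_pct  thick_fraction_pct
control_0 control                2.569               0.000
control_1 control                2.936               0.000
control_2 control                2.280               0.000
control_3 control                3.251               0.000
control_4 control                3.046               0.000
  arpkd_0   arpkd               21.265              19.807
  arpkd_1   arpkd               22.996              21.517
  arpkd_2   arpkd               20.675              18.912
  arpkd_3   arpkd               21.072              19.612
  arpkd_4   arpkd               21.085              20.563

             metric  mean_a  mean_b  t_statistic  p_two_tailed significance
volume_fraction_pct 21.4186  2.8163      42.1219           0.0          ***
 thick_fraction_pct 20.0820  0.0000      45.1528           0.0          ***
```

The control group recovers its planted ~3% collagen volume fraction and
contains no bundle with local thickness ≥ 6 μm; the fibrotic group reads
out a much larger volume fraction (segmentation of the blurred, noisy
stacks slightly dilates the 17% ground truth) of which nearly all voxels
belong to ≥ 6 μm bundles. Both group differences are highly significant.

The same stages are available from the shell:

```bash
fibroquant phantom  --config phantom.yaml --seed 3 --out phantom/
fibroquant segment  --in stack.tif --low 30 --high 60 --pixel-size-um 0.5 --z-step-um 0.5 --out mask.tif
fibroquant thickness --mask mask.tif --out tau.tif
fibroquant quantify --mask mask.tif --thickness tau.tif --thick-um 6 --out results.csv
fibroquant score    --col col.tif --ck8 ck8.tif
fibroquant run      --config run.yaml
```

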