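# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `fibroquant`.

## Segmentation model

SHG intensity stacks are preprocessed slice by slice: a mean filter with a
square block (default 5 px, edge replication at borders, no mixing across
z) suppresses shot noise; a Gaussian first-derivative gradient magnitude
(also per slice) is available as an edge-highlighting diagnostic but does
not, by default, feed the threshold — the default pipeline thresholds the
mean-filtered intensity, and the choice is exposed in configuration
because either ordering is defensible.

Binarization is two-threshold hysteresis. With thresholds t_low ≤ t_high,
the collagen mask is

    {v ≥ t_high} ∪ {t_low ≤ v < t_high connected, via a path of voxels
    all ≥ t_low under the chosen connectivity, to some voxel ≥ t_high}.

Implementation: connected components of {v ≥ t_low} (scipy labeling with a
6/18/26-connectivity structuring element; default 26, the conservative
full-3D choice), keeping components that contain a seed ≥ t_high. Paths do
not wrap around the volume border. The low/high values are required
configuration: there is no universally correct pair, and reproducible
reporting demands explicit values. Two labeled heuristics are provided —
`percentile` (thresholds as percentiles of the nonzero intensities) and
`otsu_scaled` (t_high = Otsu threshold, t_low = α·t_high, α default 0.5).
The resolved absolute thresholds are always recorded in the mask
provenance.

## Distance transform

The squared Euclidean distance transform is computed exactly with the
separable Saito–Toriwaki scheme: three 1D passes, one per axis, each
taking the lower envelope of parabolas

    D²_new(i) = min_j D²(j) + ((i − j) · s_axis)²

with s = (Δz, Δxy, Δxy) in μm. Each pass is an exact minimization (the
vectorized implementation evaluates all (i, j) pairs per line, chunked to
bound memory), so the composition is the exact squared distance between
voxel centers — no chamfer approximation. Distances are center-to-center.

Border policy: voxels outside the field of view are **not** background by
default, so fibers truncated by the FOV are not artificially thinned at
the border; `border_background=True` pads the volume with one background
shell (equivalent to virtual background voxel centers one spacing outside)
for applications that need the opposite convention. An all-foreground mask
with the default policy has no defined distance and raises an explicit
unbounded-distance error.

The `DistanceMap` container stores both the exact squared field (μm²) and
its square root (μm); oracle comparisons are made on the squared field.

## Local thickness

Thickness follows the largest-inscribed-sphere (Hildebrand–Rüegsegger)
definition implied by the standard Local Thickness routine:

    τ(p) = 2 · max{ D(c) : c foreground, ‖p − c‖ ≤ D(c) }

for foreground p, 0 elsewhere (a background voxel lying exactly on a
sphere boundary is clamped to 0). Computation is by sphere painting from
the **distance ridge**: a foreground voxel p is pruned only when some
26-neighbor q satisfies D(q) ≥ D(p) + ‖p − q‖ + ε (its inscribed sphere
strictly contains p's). Containment is transitive and strictly increases
D, so every pruned sphere is covered by a kept one, and painting from the
ridge is bit-identical to painting from all foreground voxels — an
equality the test suite asserts exactly. The margin ε = 1e-9 μm guards the
pruning against float rounding; it can only enlarge the ridge, never
invalidate it. Coverage tests during painting are made in the exact
squared domain (‖p − c‖² ≤ D²(c)), which fixes the tie-handling at sphere
boundaries unambiguously.

A `mode="2d"` option computes per-slice disk thickness for workflows that
ran the routine slice-wise; the output is labeled with the mode used
(default and recommendation is 3D).

Discretization accuracy: a continuous interface can fall anywhere within a
voxel, so thickness of a digital structure of true diameter d is
reproduced to within about one voxel diagonal (√(Δz² + 2Δxy²)); the test
suite requires ≥95% of tube/ball voxels within that tolerance, and this is
the resolution limit to keep in mind when the 6 μm thick-fiber threshold
sits close to the voxel size.

## Reported quantities

- Collagen volume fraction: 100 · |mask| / |stack| — exact integer counts.
- Thick-fiber fraction: 100 · |{τ ≥ 6 μm}| / |stack|. **The denominator is
  the total voxel count of the stack, not the collagen voxels**; with a
  fiber-voxel denominator the values would be severalfold larger, so the
  convention is stated here prominently and recorded in results.
- Periphery restriction: the analysis mask is intersected with the set of
  organoid-body voxels whose distance to the body's exterior is < 50 μm
  (depth configurable; depth 0 keeps nothing). The body mask is either
  supplied or estimated by Otsu thresholding of the Gaussian-smoothed
  intensity followed by morphological closing and hole filling — an
  explicit, provenance-recorded heuristic, since "peripheral" must be
  delimited somehow.
- Channel volume: Σ over slices of positive area × Δz, algebraically equal
  to voxel count × voxel volume.
- Fibrosis score: COL1A channel volume / CK8 channel volume on
  co-registered masks. A zero CK8 volume raises an explicit
  undefined-score error rather than returning infinity. Stacks with fewer
  than 100 slices are accepted with a logged note, since the reference
  workflow used ~100-slice whole-mount stacks.
- Area fraction (2D histology): a scribble-supervised random-forest pixel
  classifier (100 trees, fixed seed, per-pixel features: raw channels plus
  Gaussian smoothings and gradient magnitudes at σ ∈ {1, 2, 4, 8} px)
  produces per-class probability maps; P(class) ≥ 0.5 (configurable) is
  binarized and the exact positive-pixel fraction reported. The forest is
  a pluggable choice: the aim is the probability-map → threshold →
  binarize workflow, not bit-compatibility with any particular GUI tool.

## Statistics

Two-tailed unpaired t-tests; pooled-variance Student's statistic by
default (df = n_a + n_b − 2), Welch with Satterthwaite df as an option;
the variant is always recorded. Degenerate zero-variance input: equal
means → t = 0, p = 1 by convention; unequal means → ±inf, p = 0, flagged
as degenerate. Significance is annotated *p<0.05, **p<0.01, ***p<0.001,
with no multiple-testing correction (stated in the report footer). Report
rows carry an explicit unit-of-replication field (stack, organoid, image)
rather than assuming one.

## Phantom generator

Fibers are constant-radius tubes around polyline centerlines. Random
fibers follow a gentle random walk: uniform start, uniform initial
direction, Gaussian angular jitter (SD 0.25 rad) per 2 μm step, default
length 1.2× the largest volume extent so fibers span the field of view.
Voxelization rule: a voxel is foreground iff its center lies within the
radius of the centerline (point-to-segment distance in physical μm) —
unambiguous and oracle-checkable, with analytic volume πr²L for straight
tubes. Overlapping fibers union their masks; per-voxel labels attribute
overlap voxels to the thickest covering fiber.

The intensity model is: constant emission per fiber, Gaussian PSF blur
(σ in μm, isotropic in physical units), flat background, optional Poisson
shot noise (scaled photon counts), additive Gaussian read noise, clamped
at zero. One named RNG stream seeded from the spec's seed drives placement
and noise in a fixed order, so equal spec ⇒ bit-identical phantom.

When a target volume fraction is requested, fibers are added until the
achieved fraction is within the tolerance (default 1 percentage point);
fibers that would overshoot past target + tolerance are rejected and
resampled, and exceeding the attempt cap raises an error naming the
achieved fraction.

Two named regimes parameterize the study conditions: *control-like*
(target 3% volume fraction, diameters uniform 0.8–1.4 μm — all below the
1.5 μm "thin" bound) and *disease-like* (target 17%, a 60/40 mixture of
thin fibers and 6–8 μm bundles), both with background 10, Gaussian read
noise SD 5 and PSF σ 0.2 μm on an arbitrary fiber-intensity scale of 100.
No fiber-intensity statistics exist to calibrate against, so the intensity
scale is a free parameter and is deliberately not tuned to resemble any
particular dataset.

What the phantoms do **not** emulate: SHG physics (polarization,
coherence, directional emission), fiber bundling/branching, intensity
variation along a fiber, depth-dependent attenuation, or anisotropic PSFs.
Passing phantom tests therefore demonstrates correctness of the geometry
and measurement pipeline, not robustness to every property of real
microscopy.

## Problem sizes and defaults in the validation suite

Oracle comparisons use 200 random volumes up to 16³ (isotropic and 3:1
anisotropic). Phantom-based validation uses 128 × 128 × 20 stacks at
0.5 μm isotropic spacing — a deliberately reduced analogue of the study's
~1500² × (15–71) acquisitions at ~0.1 μm that preserves the
physical-units logic (the 6 μm threshold is 12 voxels here) while keeping
the suite fast; group comparisons use 10 stacks per group under multiple
seeds. Hysteresis thresholds for phantom runs are absolute (30/60 on the
0–~110 intensity scale) because the phantom intensity scale is known by
construction.

## Known limitations

- The vectorized exact EDT is O(n·m) per line per axis; at the package's
  validation sizes this is fast, but very large stacks (≥ 1500² × 70)
  would benefit from the O(n) envelope scan, which was not needed here.
- Sphere painting cost grows with ridge size and sphere radius; extremely
  dense masks at fine sampling are slower than specialized C plugins.
- The hysteresis thresholds of the original acquisitions are unknown, so
  absolute reproduction of any published fraction from raw data would
  require re-stating thresholds; all modes record the resolved values to
  make that explicit.
- The pixel classifier is deterministic given a seed but is not intended
  to replicate any specific GUI classifier's decision boundaries.
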