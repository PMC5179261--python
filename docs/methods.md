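# Methods note

This document describes the image-analysis model implemented by
`tubulequant`, the assumptions behind it, every tunable parameter with
its default and rationale, what the built-in synthetic scene generator
does and does not emulate, the numerical choices that matter for
reproducibility, and the known limitations.

## 1. Problem and model

The tool quantifies **endosomal tubulation**: thin, curvilinear
membrane tubules emanating from SNX1-positive endosomes in single
cells, imaged by two-channel widefield fluorescence microscopy. Input
is a two-channel TIFF per cell — a *cell channel* (whole-cell stain,
used only to delimit the analysis region) and a *marker channel*
(SNX1-like endosomal marker containing puncta and tubules).

A tubule is modelled as a **curvilinear bright ridge** in the marker
channel whose skeletonised centreline is longer than a fixed physical
threshold (default 2 µm, i.e. strictly more than 20 px at
0.1 µm/px). Everything shorter — puncta, blobs, short fragments — is
not a tubule. The per-image pipeline is:

1. **Cell mask** from the cell channel: Gaussian blur (σ = 5 px) →
   Otsu threshold → fill holes → discard regions < 500 px. All
   subsequent analysis is restricted to this mask.
2. **Marker enhancement**: rolling-ball-style background subtraction
   (grey opening, box footprint of half-width 50 px, edge-padded) →
   radius-1 median despeckle → Gaussian smoothing (σ = 1 px) →
   percentile contrast stretch to [0, 1] (0.3 % saturation).
3. **MTOC confound removal** (optional, on by default): the
   perinuclear cloud of endosomes around the microtubule organising
   centre is so dense that after thresholding it merges into large
   blobs whose skeletons read as spurious long branches. It is
   detected on the *enhanced* image as a compact region of extreme
   marker density (§3) and excised from the binary image before
   skeletonisation.
4. **Binarisation**: Otsu threshold computed over in-mask pixels
   only; output is always a subset of the cell mask. Small holes
   (≤ 4 px) are filled so that 1-px enclosed holes cannot block
   thinning.
5. **Skeletonisation and branch measurement**: topology-preserving
   thinning (Zhang–Suen, via scikit-image), then the skeleton is
   traced into a branch graph (§2) and every branch is measured
   geodesically.
6. **Tubule classification**: a branch qualifies as a tubule iff its
   geodesic length is **strictly greater** than the threshold
   (default 20 px).

Cohort level, three metrics summarise each experimental condition:

- **mean tubules per image**;
- **percentage of images with ≥ 1 tubule**;
- **mean longest-tubule excess** — per image, the length of the
  longest qualifying branch *minus* the threshold, converted to µm
  (0 for images without a tubule by default).

Between a designated positive and negative condition the tool reports
the **Z′-factor** for each metric, computed on *per-repeat means* (the
biological repeat is the replicate unit), plus paired (default) or
unpaired t-tests across repeats.

## 2. Skeleton branch graph and geodesic length

The traced skeleton graph is the core measurement step and is
implemented from first principles (no skeleton-analysis dependency),
with an independent brute-force oracle in the test suite.

- Skeleton pixels are classified by 8-connected neighbour count:
  **endpoints** (1 neighbour), **slab** pixels (2), **junction**
  pixels (≥ 3). Mutually adjacent junction pixels are merged into a
  single **junction cluster** that acts as one graph node; thinning
  routinely produces 2–3-px junction clumps and treating each pixel
  as a node would fragment branches.
- A **branch** is a maximal pixel path between two nodes (endpoint or
  junction cluster) through slab pixels. Its **geodesic length** is
  `n_axial + √2 · n_diagonal` over the steps of the path — a run of
  *n* pixels in a straight axial line measures *n − 1*. This is the
  standard polyline length of the pixel-centre chain.
- Branches whose two ends land on the same node (loops) are flagged
  `is_loop`; their length is still the traced polyline length.
- **Spur pruning** (default `prune_px = 2`): endpoint-to-junction
  branches shorter than 2 px are thinning artefacts and are removed,
  after which the component is *re-thinned* and re-traced (removing a
  spur can leave its junction pixel protruding as a new spur).
- A skeleton containing a solid 3×3 block is rejected
  (`NonThinSkeletonError`) rather than mis-measured; the pipeline's
  small-hole filling before thinning prevents the known cause
  (1-px enclosed holes blocking thinning).

The acceptance suite checks every traced branch on hundreds of random
thin skeletons against a Dijkstra shortest path over the branch's own
pixel graph (weights 1/√2) and requires **exact** agreement, plus
hand-computable fixtures (straight line, diagonal, T-shape).

## 3. MTOC detection

On the enhanced marker image, within the cell mask:

1. Heavy Gaussian blur (`density_sigma_px = 15`) turns puncta density
   into a smooth field.
2. Candidate core = pixels above the `density_quantile = 0.99`
   quantile of in-mask density; keep the largest connected region if
   it is ≥ `min_area_px = 300`.
3. **Absolute peak gate**: the candidate is accepted only if its peak
   blurred density is ≥ `min_peak_density = 0.3` of the image-wide
   maximum. A compact saturated cluster blurs to ≈ 0.9 of the
   maximum at σ = 15, whereas thin tubules and isolated puncta blur
   to ≈ 0.1, so this gate separates "there is a dense cluster" from
   "the top 1 % of a flat field". Without it, a pure quantile rule
   always returns a region, even for uniformly scattered puncta.
4. **Halo growth**: the accepted core is grown by hysteresis to the
   connected component above the `halo_quantile = 0.9` density
   quantile that contains it. Excising only the bright core leaves a
   bright annulus whose arcs skeletonise into fake tubules; growing
   to the halo removes the whole confound.
5. The result is dilated by `dilation_radius_px = 10` and subtracted
   from the binary image.

Detection can be disabled (`--no-mtoc-removal` / `[mtoc] enabled =
false`); the validation module quantifies the effect on matched
zero-tubule MTOC scenes (0 vs 81 false-positive tubules over 20
scenes at seed 1).

## 4. Parameters

All defaults live in frozen dataclasses and in the TOML emitted by
`tubulequant config-init`.

| Parameter | Default | Why |
|---|---|---|
| `pixel_size_um` | 0.1 | Typical 63×/1.4 NA widefield sampling; makes 20 px = 2 µm. |
| `min_tubule_length_px` | 20 | 2 µm operational definition of a tubule at the default pixel size. |
| `strict_threshold` | true | A branch of exactly threshold length does not qualify ("longer than"). |
| `tubule_unit` | `branch` | Count each qualifying skeleton branch; `component_max_path` instead counts one tubule per connected component using its weighted-diameter path. |
| `excess_metric_empty_images` | `zero` | Images without tubules contribute 0 excess (keeps the metric defined on every image); `exclude` averages over tubule-bearing images only. |
| `zprime_denominator` | `difference` | Standard Z′ separation band 1 − 3(σ₊+σ₋)/\|x̄₊−x̄₋\|; `as_printed_sum` uses (x̄₊+x̄₋) instead, for comparison with reports that use that form. |
| `cell_mask_sigma_px` / `cell_mask_min_region_px` | 5 / 500 | Blur scale of a whole-cell stain; 500 px ≈ 2.2 µm² floor removes debris. |
| `prune_px` | 2 | Removes 1-px thinning spurs without touching real short branches. |
| `background_radius_px` | 50 | Larger than any tubule width/punctum (≤ ~4 px) and smaller than cell-scale background structure. |
| `smooth_sigma_px` | 1.0 | Matches the PSF scale; suppresses pixel noise without merging parallel tubules. |
| `despeckle_radius_px` | 1 | Radius-1 median removes single hot pixels exactly. |
| `contrast_saturation_fraction` | 0.003 | Standard 0.3 % percentile stretch; robust to a few saturated pixels. |
| `threshold_method` | `otsu` | Parameter-free, computed over in-mask pixels only. |
| MTOC: `density_sigma_px` 15, `density_quantile` 0.99, `halo_quantile` 0.9, `min_area_px` 300, `min_peak_density` 0.3, `dilation_radius_px` 10 | see §3 | Scaled to a ~3.5 µm perinuclear cluster at 0.1 µm/px. |

## 5. Synthetic scene generator

`tubulequant.synth` generates two-channel scenes with exact ground
truth so every claim is testable without real data.

**Emulated:** a single bright cell silhouette on dark background;
Gaussian endosomal puncta (delta-stamped then blurred once, so
amplitude is exact); curvilinear tubule centrelines as unit-step
random walks with bounded per-step heading change (`tubule_curvature`
spans straight to strongly curved; unit steps make ground-truth arc
length equal the step count exactly); an optional dense MTOC cluster
offset ~0.35·R from the cell centre (perinuclear); a linear
background gradient; optical blur (Gaussian PSF, σ = 1 px); camera
noise (Poisson shot noise + Gaussian read noise, sd 2); float32 TIFF
round trip that is bit-identical.

**Not emulated:** 3-D defocus and out-of-focus haze (the PSF is a 2-D
Gaussian), multiple/touching cells, photobleaching, tubule branching
or varicosities, non-uniform illumination beyond a linear ramp,
chromatic offsets between channels, fixed-pattern sensor noise.

Presets: `control-like` (Poisson mean 0.5 tubules, 1–2.5 µm),
`depleted-like` (mean 3, 2.5–8 µm — fission-factor-depletion-like),
`straighter-longer` (mean 3, 4–10 µm, curvature 0.08), and
`mtoc-confound` (no tubules, MTOC cluster on). The `fig3-like` cohort
preset pairs `control-like` against `depleted-like`.

**Seeding:** every per-image seed is derived as
`blake2b(base_seed, *labels) mod 2³¹`, so cohorts are reproducible
from one integer, stable across processes, and independent of
generation order.

Ground-truth matching (`tubule_recovery`): a traced branch matches a
truth centreline when ≥ 50 % of its pixels lie within 4 px of the
centreline (cKDTree); sensitivity is reported for truth tubules of
arc length ≥ 3 µm, comfortably above the 2 µm decision boundary so
the number measures detection, not threshold jitter.

## 6. Numerical choices

- **Geodesic length convention**: *n* collinear pixels measure
  *n − 1* (distance between end pixel centres), so the 2 µm rule is
  "21 axial pixels do not qualify at threshold 20, 22 do". Diagonal
  steps count √2.
- **Background subtraction** uses a box grey opening rather than a
  disk: on 1024² images the disk decomposition took ~1.8 s/image vs
  0.09 s for the box with no measurable effect on detection. The
  image is padded by the footprint radius (edge mode) before the
  opening so intensity ramps do not leave a residual band at the
  borders.
- **Despeckle before smoothing**: a radius-1 median can only remove a
  hot pixel while it is still an impulse; Gaussian smoothing first
  would spread it into a blob the median keeps.
- **Otsu over masked pixels only**; empty or zero-variance masks give
  an all-false foreground instead of a meaningless threshold.
- **Z′ on per-repeat means**: the repeat is the replicate unit, so σ
  in Z′ is the sd (ddof = 1) across repeat means, not across images.
  With 3 repeats × 15 images/condition this puts the default
  two-condition synthetic screen near the 0.5 "robust" boundary by
  design of the presets, not by tuning; larger cohorts move it up.
- **Strictness and determinism**: all stochastic code takes explicit
  seeds; analysis of the same TIFF is byte-identical across runs;
  CSV floats are written with `%.6g`.
- **Problem sizes** used in validation: full-scale scenes are
  1024×1024 px (102 µm field, cell radius 30 µm); the standard screen
  is 2 conditions × 3 repeats × 15 images; the ablation uses 20
  matched MTOC scenes.

## 7. Limitations

- Single-cell, single-plane 2-D analysis; overlapping cells or thick
  samples violate the model.
- Crossing or touching tubules merge into one skeleton component;
  with the default `branch` unit the pieces between junctions are
  counted separately, which can over-count at high tubule density.
- The fixed 2 µm threshold is an operational definition; near-2 µm
  tubules flicker across the boundary with noise (hence the
  strictly-greater rule and the ≥ 3 µm sensitivity report).
- MTOC removal excises a region; a real tubule running through the
  perinuclear halo is lost with it.
- Otsu assumes a bimodal in-mask intensity histogram; images with no
  marker signal at all are handled (empty foreground) but images with
  strong non-endosomal background texture may threshold poorly — use
  `threshold_method = "fixed"` with a calibrated value in that case.
- The synthetic generator validates the *algorithm*, not any specific
  microscope: absolute intensities and noise levels approximate, not
  reproduce, a particular acquisition.
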