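# Methods

This note documents the models and procedures implemented in `roicell`,
their assumptions, the defaults that matter, and the design choices made
where the problem was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## ROI detection and cropping

Exported DSP ROI images are square rasters with the circular ROI on a
near-white margin. The detector thresholds the margin (all channels
`≥ 255 − background_tol`, default tolerance 10), takes the largest
connected non-background component, and fits an **area-equivalent circle**:
center = component centroid, radius = `sqrt(area/π)`, both rounded to
integer pixels. Rounding makes re-cropping exactly idempotent (the
re-detected centroid and area-equivalent radius of a rasterized disc round
back to themselves), at a sub-pixel cost far below the ±2 px accuracy the
pipeline needs. The image is cropped to the circle's tight bounding square
and pixels outside the circle are set to **white** (255,255,255) — not
zero, which would contaminate the blue/DNA channel statistics — and are
additionally excluded from every downstream computation via `roi_mask`.

If the foreground touches all four image borders the image is assumed
already cropped: a warning is emitted and only masking is applied. Physical
scale is unknown unless the caller asserts the vendor ROI diameter (e.g.
300 µm), in which case `um_per_px = diameter / (2 · radius_px)`; otherwise
all spatial statistics are reported in pixels.

## Segmentation

Segmentation is a backend registry behind one contract: backend(image,
params) → integer label raster. The shipped `reference` backend is a
deterministic classical segmenter parameterized by the expected cell
diameter `d` (default 23 px, matching ~1 µm/px exports):

1. Gaussian smoothing of the nuclear (blue) channel, `σ = d/8`;
2. Otsu threshold computed over in-ROI pixels (near-white sentinel pixels
   are suppressed first — white is margin, never nuclear signal);
3. Euclidean distance transform, peak markers with minimum separation
   `d/2`;
4. marker-controlled watershed; components smaller than `(d/4)²` pixels
   removed; labels compacted to 1..n.

Cells whose centroid falls outside the ROI circle are dropped (margin
artifacts cluster at the rim). The `flow_threshold` parameter is carried
for neural backends that use it; the reference backend ignores it. The
backend is exact-deterministic: same input, same label raster.

On rendered fixtures the matched diameter for ~4 px-radius cells after the
1 px optical blur is 13 px; with it the backend recovers planted
non-touching counts of 20–500 cells within 5% (typically within 1%). No
segmentation-accuracy claim is made beyond count recovery on these
fixtures: real tissue has touching cells, intensity gradients, and staining
artifacts the renderer does not emulate.

## Morphology

Per-cell features: centroid (unweighted pixel mean; x = column, y = row,
0-based), mean R/G/B intensity over member pixels, pixel count, area
(= pixel count, px² units), perimeter, circularity. Perimeter uses the
**Crofton approximation** (4 directions): boundary-pixel counting
systematically overestimates perimeters of small rasterized discs and
pushes circularity above 1. Circularity is `4πA/P²`, 1 for a perfect
circle; rasterization can still push small shapes slightly above 1, so the
documented bound is `(0, 1.1]`. Features are in pixels; conversion to µm
happens only when `um_per_px` is known.

## Cell typing

The marker channel (green) is bimodal across cells in well-stained data;
three classifiers are provided over per-cell mean intensities:

* **cutoff** — strict `>` (a cell exactly at the cutoff is negative, a
  fixed documented tie-break). The default cutoff is 20 intensity units;
  published workflows on comparable data have used values between 10 and
  20, so the cutoff is an explicit, always-visible parameter rather than
  anything auto-selected.
* **gmm** — a seeded scikit-learn Gaussian mixture (default 2 components,
  seed 0, 3 initializations) on the selected channels; the component with
  the **highest mean on the marker channel** is positive (never component
  index, which is fit-dependent). For the 1-D two-component case the
  reported threshold is the posterior-0.5 crossing between the component
  means (bisection); in 2-D it is NaN.
* **kmeans** — seeded K-means with the same component-to-class mapping;
  `k=1` labels everything positive with a warning.

Degenerate GMM fits fall back to a cutoff at the midpoint of the component
means, with a warning. Degeneracy is declared when a component variance
reaches the regularization floor **or** a single-component fit achieves an
equal-or-better BIC — the latter is what actually catches unimodal data,
where a two-component fit converges to two overlapping finite-variance
halves that a variance test alone would miss. On well-separated mixtures
(mode separation ≥ 4 pooled SDs) all three methods agree with ground truth
on ≥ 97% of cells and with each other.

## Cross-K mixing score

For a marked pattern with `n₊` positive and `n₋` negative points in a
circular window `W`:

```
K̂_cross(r) = |W| / (n₊ n₋) · Σ_{i∈pos} Σ_{j∈neg} w_ij · 1[d_ij ≤ r]
```

Under independence of the two populations `K_cross(r) = πr²`. The **AUC
mixing score** is `∫ (K̂(r) − πr²) dr / r_max²` by the trapezoid rule over
`n_r = 100` equally spaced radii ending at `r_max` (default: window
radius / 4, the common default of reference implementations). The score is
signed: segregation must rank below complete spatial randomness, so it is
not clipped at zero. Normalizing by `r_max²` makes scores comparable
across ROIs of different sizes.

Edge corrections: `translation` (default) uses the exact disc–disc overlap
weight `w_ij = |W| / |W ∩ W_{+v_ij}|`, which for a disc depends only on the
pair distance; `border` is the reduced-sample estimator; `none` is the raw
count (and is what the O(n²) brute-force oracle computes, used to verify
the vectorized estimator to 1e-9). The translation-corrected estimator is
exactly symmetric under mark swap; the symmetric average of both
directions is also exposed. Grouping into Mixture/Separative requires an
explicit rule — `top_n` (ties broken lexicographically by ROI id) or a
threshold — because no universal cutoff exists; ranking, the score's
actual use, is robust to the estimator choices above.

The analytic Poisson curve `πr²` is used as the reference rather than a
simulated envelope mean; for a homogeneous window the two coincide in
expectation and the analytic curve adds no Monte-Carlo noise.

## Expression preprocessing

Order is fixed: probe aggregation → segment filter → gene filter → Q3
normalization; both filters are idempotent, and so is Q3 normalization
(after normalization all Q3s equal their geometric mean).

* **Aggregation**: gene value = arithmetic mean of its probes per segment;
  every probe must map to exactly one gene.
* **Detection** is an input: a boolean matrix or an LOD threshold (default:
  value > 0). Vendor negative-probe LOQ models are out of scope.
* **Segment filter**: drop segments detecting `< 5%` (strict) of the genes
  detected *anywhere in the current matrix* — the detected-anywhere
  denominator, not the panel size, is the implemented reading.
* **Gene filter**: keep genes detected in `≥ 10%` of remaining segments.
* **Q3**: factor `f_s = Q3_s / geomean(Q3)` with the 75th percentile
  computed by linear interpolation between order statistics; dividing by
  `f_s` keeps the matrix on its original scale. A zero Q3 is an error
  naming the segment. Within-segment gene ranks are preserved.

## Ligand–target pair prediction

For each group of segments (≥ 3 required), every (ligand, target) row of
the curated table whose provenance is not `ppi_prediction` and whose genes
are both present is tested: Pearson correlation across the group's
segments on the normalized matrix, retained when `r > 0.75` (strict).
Correlating only table pairs is mathematically identical to the all-pairs
correlation matrix intersected with the table (kept as a test oracle). No
multiple-testing correction is applied — the procedure is a pure
correlation filter, and with ~10–20 segments per group the correlations
are descriptive, not inferential. The table loader accepts either a
`source_kind` column or a raw source column plus the set of source names
that count as PPI prediction; the published resource itself is not bundled.

## Synthetic fixtures: what they emulate, and what they do not

* **Images**: anti-aliased elliptical cells (axis ratio ≤ 1.25), additive
  channel intensities clipped at 255, 1 px Gaussian blur for optical blur;
  blue nucleus (inner 70% of the cell) in every cell, class-specific green
  (defaults 60 ± 8 vs 8 ± 2) and red means. Default geometry mirrors a
  typical export: 600×600 px, ROI radius 150 px, 535 cells (258 positive).
  Non-overlapping placement uses a jittered grid with a guaranteed gap —
  needed for count ground truth — and therefore caps the density; the
  1100 px / radius-520 canvas used for the 500-cell fixture reflects that
  cap, not a platform geometry. Not emulated: tissue texture,
  autofluorescence, scanner noise, touching/overlapping nuclei under the
  non-overlap flag — so passing counts say nothing about crowded tissue.
* **Patterns**: CSR = uniform in the disc; attraction = negatives uniform
  within a distance (default 5 px) of a random positive; segregation =
  marks folded onto opposite half-discs. These are calibration regimes,
  not tissue models.
* **Expression**: log-normal baseline (per-gene log2 mean uniform in
  [3, 9], biological log2 SD 0.5), log-normal per-segment scale factors
  (log2 SD 0.4), 2–4 probes per gene with 0.05 log2-SD efficiencies;
  planted pairs share a latent factor so the log-scale correlation equals
  the requested `r` (the linear-scale Pearson is within a few percent at
  these variances). Scale-recovery checks use a 1000-gene panel: Q3 is a
  quantile, and its sampling noise at ≲300 genes is comparable to the
  planted scale spread, whereas real panels are thousands of genes. A
  planted common scale also induces spurious positive correlation between
  all genes — exactly what Q3 normalization removes, which the decoy pairs
  in the RL tests exercise.

## Numerical and degenerate-input conventions

* 16-bit TIFFs are rescaled by `round(v / 65535 · 255)`; alpha dropped.
* Uniform (no-contrast) images segment to zero cells rather than erroring.
* Cross-K requires ≥ 2 points per mark (the brute-force oracle allows 1);
  `r_max` may not exceed the window radius.
* All stochastic components (generators, GMM, K-means) take explicit seeds
  and are reproducible bit-for-bit; the CLI exposes `--seed`.
* Problem sizes in the tests and acceptance script (100-seed pattern
  batches, 26-ROI grouping corpus, 500-cell segmentation canvas, 1000-gene
  panels) were chosen as the smallest sizes at which the statistics they
  calibrate are stable; all run in seconds on one CPU.

## Known limitations

* The reference segmenter is a nuclei-driven watershed: it undercounts
  heavily overlapping cells and has no concept of cytoplasm boundaries.
* Cell typing is binary (marker-positive vs negative); multi-marker typing
  and spillover correction are out of scope, and the red channel is not
  classified on (it is not reliably bimodal in warm-biased RGB exports).
* The AUC score uses a single radius range; no envelope tests or
  inhomogeneous-intensity corrections are provided.
* Expression preprocessing assumes detection calls are given; no
  background model, batch correction, or differential expression.
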