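# roicell

Cell-level analysis of circular ROI images from digital spatial profiling
(DSP) platforms, and of the matched ROI expression matrices.

In GeoMx-style DSP experiments, a pathologist selects circular regions of
interest (~300 µm across) on a slide stained with multiplex
immunofluorescence — a DNA dye (blue), an epithelial/tumor marker such as
pan-cytokeratin (green), and an immune marker such as CD45 (red) — and each
ROI yields a mini-bulk transcriptome. The imaging channel is usually used
only to place the ROIs. `roicell` turns it into quantitative data:

1. **Crop** — locate the circular ROI on its white export margin and mask
   everything outside it.
2. **Segment** — per-cell label masks via a pluggable backend (a
   deterministic classical watershed backend ships with the package; neural
   segmenters can be registered under the same contract).
3. **Features** — per-cell centroid, mean R/G/B intensity, pixel count,
   area, Crofton perimeter, circularity `4πA/P²`.
4. **Classify** — marker-positive vs negative cells from the (bimodal)
   marker-channel intensity, by fixed cutoff, Gaussian mixture, or K-means.
5. **Mixing score** — the bivariate Ripley cross-K function

   `K_cross(r) = |W| / (n₊ n₋) · Σᵢ Σⱼ w_ij · 1[d_ij ≤ r]`

   against the independence reference `πr²`; the signed area between the
   two curves over a radius grid, normalized by `r_max²`, is the **AUC
   mixing score** (positive = tumor and stroma cells intermingle, negative
   = they segregate, ≈0 under complete spatial randomness). ROIs are ranked
   into *Mixture* vs *Separative* groups.
6. **Expression preprocessing** — probe-to-gene averaging, segment and gene
   detection filters (<5% of detected genes drops a segment; genes kept
   when detected in ≥10% of segments), upper-quartile (Q3) normalization
   referenced to the geometric mean of Q3s.
7. **Ligand–target pairs** — per ROI group, gene pairs from a curated
   ligand–target resource (NicheNet-like schema, PPI-prediction-derived
   rows excluded) are "predicted" when their Pearson correlation across the
   group's segments exceeds 0.75.

A synthetic-fixture module generates all three input kinds with known
ground truth (rendered ROI images, marked point patterns with controllable
attraction/segregation, expression matrices with planted scale factors and
correlations), so every stage is testable end to end.

## Worked example

```python
import tifffile
import roicell as rc

# render a synthetic ROI: 100 cells, 40 marker-positive
spec = rc.ImageFixtureSpec(n_positive=40, n_negative=60, overlap_allowed=False,
                           image_size_px=700, roi_radius_px=220, seed=12)
fx = rc.make_roi_image(spec)
tifffile.imwrite("roi.tif", fx.image)

img = rc.detect_and_crop_roi(rc.load_roi_tiff("roi.tif"))
print(f"radius_px={img.radius_px:.0f} center={img.center}")

mask = rc.segment_cells(img, rc.SegmentationParams(diameter_px=13))
cells = rc.extract_features(img, mask, roi_id="roi")
typing = rc.classify_gmm(cells, seed=0)
print(typing.summary_text())

cells["class_label"] = typing.labels
ck = rc.cross_k(rc.pattern_from_cells(cells, img.center, img.radius_px))
print(f"auc={ck.auc:.3f}")
```

prints

```
radius_px=220 center=(220.0, 220.0)
Total cells: 100 | Positive cells: 40 (40.00%)
auc=-3.928
```

All 100 rendered cells are found, the Gaussian-mixture classifier recovers
the 40 planted marker-positive cells exactly (the two intensity modes sit
at 8 and 60, so the fitted posterior boundary lands near 14), and the AUC
mixing score is negative because under the uniform placement the positive
cells show no attraction toward the negatives at these radii — on
attraction-regime fixtures (`rc.make_pattern`) the score is reliably
positive, on segregated half-disc fixtures reliably negative.

The same pipeline runs from the shell over a directory of exported TIFFs:

```sh
roicell run --config run.toml        # crop → segment → classify → cross-K → …
roicell crop --in rois/ --out cropped/
roicell synth image --out fixtures/ --seed 0
```

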