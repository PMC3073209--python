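# Methods

## Problem

A whole-slide image (WSI) is a gigapixel brightfield scan of a glass
histology slide. Scanners focus per field, and regional defocus is common
enough that slides are still checked by eye after scanning — slow work
with high inter-observer variability. slidefocus automates that check: it
scores every 128×128-pixel sub-tile of a slide with an edge-based focus
measure at full resolution, classifies sub-tiles into six
sharpness/background categories, renders the result as a color-coded
sharpness map (one map pixel per sub-tile), and grades the slide
*excellent / acceptable / review / defective*.

Two properties of the problem shape the design:

1. **Full resolution only.** Downsampling acts as a low-pass average that
   makes a defocused image look sharp, so all scoring reads the level-0
   plane of the pyramid; other levels are never consulted.
2. **Embarrassingly parallel with a merge contract.** The slide is cut
   into non-overlapping, sub-tile-aligned tiles; each tile is an
   independent unit of work. Partial results are merged by lattice
   coordinate, so the assembled grid and the verdict are bit-identical
   for any worker count and any completion order. The in-process thread
   pool here stands behind the same split/run/merge contract a
   distributed grid would use.

## Focus measures

Both measures operate on BT.601 luma (0.299 R + 0.587 G + 0.114 B), kept
in floating point, and both are normalized by evaluated-pixel count so
scores are comparable across sub-tile sizes.

**Tenengrad.** Sobel gradients `Gx, Gy` (3×3 kernels, reflect padding so
every pixel is evaluated); per-pixel energy `e = Gx² + Gy²`; score
`Σ{e > T} e / N`. The noise floor `T` suppresses sensor noise on flat
areas; default `T = 100` in squared-gradient units on 8-bit luma, i.e. a
gradient magnitude of 10 gray levels, comfortably above shot noise and
well below stained-edge gradients.

**Sum-modified-Laplacian (SML).** On interior pixels,
`ML(x,y) = |2I − I(x−s,·) − I(x+s,·)| + |2I − I(·,y−s) − I(·,y+s)|`;
score `Σ{ML ≥ t} ML / N_interior`. Defaults `s = 1`, `t = 7` (8-bit
scale), the common autofocus operating point. SML is the reference
measure in published autofocus comparisons; Tenengrad is the default
here for its robustness/runtime balance.

Numerical notes: thresholding subsets a sum of non-negative terms, so the
score is non-increasing in the threshold up to float summation order
(~1e-16 relative); both measures are exactly invariant to adding a
constant to all pixels; vectorized implementations agree with
brute-force nested-loop references to < 1e-9 relative error.

## Background detection

Bare glass in brightfield H&E is near-white and colorless. A pixel is
background when luma ≥ 220 **and** HSV-style saturation
`(max−min)/max ≤ 0.10` (saturation taken as 0 for black). The
conjunction matters: overexposed but stained pixels fail the saturation
limb, bright-pink eosin fails both. A sub-tile with ≥ 90% background
pixels is *pure background*; a tissue sub-tile with ≥ 50% is flagged
"high percentage of background". All four constants are config-exposed
and echoed into every report.

## Classification

Per sub-tile, with thresholds `t_blur < t_sharp`:

- `bg_fraction ≥ 0.90` → **background** (regardless of score);
- `score ≥ t_sharp` → **sharp** (or **sharp_bg** if high-background);
- `score < t_blur` → **blurred** (or **blurred_bg**);
- otherwise → **medium**.

Ties at a threshold resolve to the better class (≥ at upper bounds, <
at the lower), deterministically. High-background sharp/blurred tiles
count as tissue, not background: they contain assessable tissue.

Per slide: `blurred_fraction = (blurred + blurred_bg) / tissue`, where
tissue excludes only pure background and medium counts as tissue but not
blurred (conservative: only clearly defocused area drives the verdict).
Verdict bounds default to excellent ≤ 0.02, acceptable ≤ 0.10, review
≤ 0.30, defective above — the four named classes are standard; the
cut-offs are this package's defaults, config-exposed and echoed in the
report. A slide with zero tissue sub-tiles is sent to *review* with a
`no_tissue_detected` flag rather than given a focus verdict it cannot
earn.

## Threshold calibration

Absolute focus scores depend on scanner optics, stain, and measure, so
`calibrate_thresholds` derives `t_sharp`/`t_blur` from the synthetic
generator: `n` seeded 128×128 tissue textures are scored in focus
(σ = 0) and defocused (σ = 3); `t_sharp` is the 25th percentile of the
sharp-condition scores and `t_blur` the 75th percentile of the
blur-condition scores. With the default generator the two distributions
are far apart (Tenengrad: sharp ≈ 28 000–38 000, blurred ≈ 3 800–5 200
over 100 seeds), so the band between the thresholds is wide and the
quartile placement is uncritical. If the conditions ever overlap, both
thresholds collapse to their midpoint with a warning.

By construction of a rank-based rule, roughly a quarter of genuinely
sharp sub-tiles score below the 25th-percentile `t_sharp` and land in
*medium* — the six-way map deliberately keeps that uncommitted band for
visualization. When the ternary question (sharp tissue / blurred tissue
/ background) must be answered, e.g. against ground truth,
`coarse_label` resolves medium-band scores at the band midpoint
`(t_sharp + t_blur)/2`. Given the disjoint score distributions this is a
decision rule, not a tuned constant: any cut anywhere inside the wide
empty band gives the same answer.

## Synthetic slides

The generator emulates exactly the image features the pipeline measures,
with per-sub-tile ground truth:

- **Tissue**: eosin-like base (235, 190, 200) with Gaussian noise
  (σ = 4), overlaid with ~40 dark elliptical hematoxylin-like blobs
  (90, 60, 140; semi-axes 4–12 px) per 128×128 patch. Blob edges supply
  the gradient content; blob-count variation across sub-tiles gives a
  realistic score spread. Mean tissue saturation (≈ 0.19) keeps tissue
  clear of the background detector.
- **Background**: near-white (245, 245, 245) with ±3 uniform noise.
- **Defocus**: per-region Gaussian blur, reflected at the region border
  so sharpness never leaks across regions. Regions are specified on the
  sub-tile lattice, so truth aligns exactly with assessment cells.
- **Truth bands**: σ < 1 is *sharp_tissue*, σ ≥ 2 is *blurred_tissue*;
  the ambiguous band σ ∈ [1, 2) is rejected by the spec validator so
  every ground-truth label is unambiguous.

Everything is a pure function of (spec, seed): regeneration is
byte-identical.

What the generator does **not** model — real optics PSFs, chromatic
aberration, stitching seams, JPEG compression, tissue folds, pen marks,
coverslip debris — bounds what passing tests show: they validate the
measures, the classification logic, and the execution contract, not the
default thresholds' operating point on any particular scanner. On real
slides the background constants and calibrated thresholds should be
reviewed against a handful of manually graded examples.

## Problem sizes and other choices

Test and verification runs use desk-scale slides — 512×512 to 1024×1024
pixels (16–64 sub-tiles), 10 slides for the parallel-determinism check,
20 seeds × 4 blur levels for monotonicity, 5 held-out 1024² slides for
recovery — sizes at which every property being checked (determinism,
order independence, conservation, monotonicity, separability) is already
fully exercised; nothing in the pipeline's logic depends on slide area.
The default worker-tile side is 2048 px (a "moderate" fetch unit; any
multiple of the sub-tile side works). Partial sub-tiles at the right and
bottom edges (< 128 px of margin) are excluded from assessment rather
than scored on a smaller window, keeping all scores comparable; the map
covers only the assessed lattice. Coordinates are 0-based, x rightward,
y downward, rectangles half-open. Supported inputs are 8-bit RGB flat or
pyramidal TIFF, PNG, and a `{level}/{col}_{row}.png` tile directory;
16-bit input is rejected rather than silently rescaled, and proprietary
WSI containers (NDPI, Mirax, JPEG2000, Zoomify) are out of scope — feed
a TIFF export instead.

## Known limitations

- Slides are currently materialized in memory for region reads; true
  out-of-core tiled TIFF reading would be needed above a few gigapixels.
- Assessment on a single focal plane cannot distinguish defocus from
  genuinely low-contrast tissue; very sparse, faintly stained tissue can
  score into the medium band.
- The fail-fast job contract returns no partial maps; for interactive
  triage of huge batches a resumable mode would be preferable.
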