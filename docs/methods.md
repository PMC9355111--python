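# Methods

## Scope and model

`steatoquant` scores hepatic macrosteatosis as an area fraction: accepted
fat-droplet pixels over liver-tissue pixels, per image, aggregated per
liver. The segmentation is a fixed sequence of classical operations —
adaptive thresholding, morphology, connected-component geometry,
watershed, and two circularity-gated classification passes — with no
learned components, so identical input and configuration always yield a
bit-identical mask.

The method's operating assumptions are worth stating explicitly:

* each image's green and blue histograms are **bimodal** above the dark
  lower bound: a pink-tissue mode and a white-space mode (droplets,
  lumina, tears, background all present as near-white because none of
  them stain);
* macrosteatotic droplets at 20× in a 640×480 frame are **round**
  (C₁ and C₂ near 1) and **between 2 and ~500 px** in area, while
  artifacts are either much larger (tears, background) or elongated
  (vessel lumina);
* the black vignette ring and out-of-field area can be recognized purely
  by darkness plus geometry (edge-connected, or a ring enclosing the
  field).

## Thresholding

Histograms are taken over non-border pixels and smoothed with a 5-bin
moving average; peaks are plateau-aware local maxima. The threshold per
channel is the mean position of the two highest peaks above the lower
bound (default 100), the intent being a cut midway between the tissue and
white modes. Two robustness guards decide what counts as a mode:

* **valley test** (`peak_valley_ratio`, default 0.5): a second peak only
  counts if the histogram dips below half its height somewhere between
  the two peaks. Sampling-noise bumps on the flank of a unimodal
  histogram fail this; a genuine white mode — however small — passes,
  because the gap between tissue and white intensities is nearly empty.
* **mass floor** (`min_peak_mass_fraction`, default 1e-5 of histogram
  mass, never below one count): a stray pixel's bin is not a mode.

If only one qualifying peak exists, its position is used as the
threshold. For an image that is *all* tissue (no white space anywhere)
this puts the cut at the tissue mode; roughly a quarter of noisy tissue
pixels binarize white, but erosion and the droplet gates reject
essentially all of it (observed residue ≤ 0.01% across seeds). Fields
with no white space at all are nevertheless outside the method's design
conditions; real biopsy fields essentially always contain unstained
area. An image with no histogram mass above the lower bound, or with
less than `min_tissue_fraction` (1%) of pixels inside the field, raises
`NoTissueError`.

A pixel is white iff **both** green and blue reach their thresholds.
H&E tissue is pink — high red, moderate green/blue — while white space is
high in both, so the conjunction is the discriminative choice; an `"or"`
variant is available behind `channel_combine` for permissive use.

## Geometry

* **CA** is the raw pixel count of an 8-connected white region.
* **MECA** is the area of the minimum enclosing circle of the region's
  boundary-pixel *corner* points (each pixel occupies its unit square).
  Using corners rather than centers makes a 20×20 square score exactly
  the analytic C₁ = 2/π and keeps MECA ≥ CA always. The circle comes
  from `shapely.minimum_bounding_radius`; tests cross-check it against a
  brute-force pair/triple search over convex-hull candidates.
* **P** is the sub-pixel marching-squares contour length at level 0.5,
  holes filled, summed over the 4-connected sub-blobs of the region.
  This matches analytic perimeters of rectangles to within corner cuts
  and gives digital disks C₂ ≈ 0.89–0.95 (approaching 1 with radius).
  A single isolated pixel would score C₂ ≈ 1.25 by this rule; it is
  unreachable in the pipeline because every gate requires area ≥ 2, and
  the circularity-bound property tests therefore start at 2 px.

## Watershed

Markers are the local maxima of the Euclidean distance transform with a
minimum separation of 5 px (`watershed_min_distance`), labeled per
connected component; watershed runs on the negated distance map
restricted to the white set, so every white pixel receives a label and
pixel counts are conserved exactly. Components that receive no marker
keep their connected-component identity. Two merged disks of radius 10
with centers 15 px apart split into two regions within 20% of equal
area; chains of three split into three.

## Scores

Per image: `100 · fat / tissue` with tissue = binarized-black, non-border
pixels + accepted fat. White pixels *rejected* as background or artifact
are excluded from the denominator — the same convention as the control
images' green/(green+black), which deliberately excludes "neither"
pixels. Per liver: mean and sample SD (ddof = 1) of the image scores are
computed once; scores inside the closed interval [m−s, m+s] are retained
and re-averaged. The retained set cannot be empty (the mean of any
sample lies within one SD of itself), the pass is single and
non-iterative, and a single image returns its own score.

Control images are classified per pixel to the nearest of three
canonical colors — green (0,200,0) fat, black tissue, gray (128,128,128)
neither — with a per-channel tolerance of 30 so mildly compressed files
still classify; off-palette pixels count as neither.

## Agreement statistics

The intraclass correlation is computed from the two-way ANOVA
decomposition (subjects × raters, complete matrix). The default reported
variant is the single-rater consistency form

    ICC(3,1) = (MSR − MSE) / (MSR + (k−1)·MSE)

with exact F-based 95% bounds; the absolute-agreement single-rater form
(ICC(2,1)-style, Satterthwaite-approximated bounds after McGraw & Wong)
is computed alongside, since which flavor a given report used is often
unstated. On the bundled expert table the consistency variant reproduces
the published-style values (strict 0.65, CI 0.29–0.89; gestalt 0.72, CI
0.40–0.91). A constant matrix raises `IccUndefinedError`; a negative
lower CI bound is reported raw with a clipped-at-zero convenience
property. Pearson r, OLS and the threshold-straddle count are standard;
the straddle rule is "at least one rater strictly above and at least one
at or below the threshold".

## Phantoms

The generator renders two image families with exact pixel truth, driven
by a single integer seed.

**H&E phantoms** emulate the features the pipeline must survive, not
histological appearance: pink tissue (200,130,150) with a per-image
jitter of ±25 per channel (to force the per-image adaptive thresholds to
actually adapt), white droplets (245–255) in a configurable radius range
(default 4–12 px, i.e. areas ~50–450 px as for macrosteatotic droplets
at this scale), irregular white tears (> 2000 px), elongated white
lumina (≥ 800 px, width/length chosen so C₁ < 0.2), dark nuclei speckle
at 2% density with all channels below the histogram lower bound,
Gaussian pixel noise (σ = 5), and an optional black vignette ring.
Droplet placement is rejection sampling with a 2-px separation margin;
with `clustering` > 0 a droplet may instead attach next to an existing
one at center distance 0.75–1.0 × the radius sum, producing merged blobs
(clusters capped at three members so a blob cannot cross the background
size gate). A `target_fat_fraction` overrides the droplet count and is
closed to within a fraction of a droplet; the stored truth is always
recomputed from the rendered pixels. Targets above 60% without
clustering are rejected as infeasible for disjoint disks.

What the phantoms do **not** emulate: real H&E texture, uneven
illumination, chromatic aberration, out-of-focus fields, microsteatosis,
and droplets merged with artifacts. Passing the recovery suite therefore
demonstrates that the pipeline's logic is faithful (artifact rejection,
droplet acceptance, denominator accounting, threshold adaptation), not
that its accuracy on real slides equals its accuracy on phantoms.

**Control phantoms** render disjoint green disks on black with gray
elliptical patches, using exactly the canonical scoring colors, so the
strict pixel estimate must equal the stored truth *exactly* — a
consistency identity between the generator and the scorer, asserted over
20 phantoms.

## Problem sizes and numerical choices

The recovery suite uses 50 H&E phantoms at 640×480 with truth fractions
evenly spanning 0–30%, two tears, one lumen and a border each — the
frame size the thresholds are stated for, and the steatosis range where
the accept/discard decision lives. Observed recovery error is ≤ 0.4
percentage points at the maximum across seeds (median 0), comfortably
inside the suite's 1.5/4.0-point bands; the bands allow for the
clustering and partial-overlap regimes where watershed splitting is
imperfect. Area thresholds rescale linearly with image area for
non-reference frames (with a warning); circularity thresholds are
scale-free. All coordinates are row-major 0-based; areas are raw pixel
counts with no physical-unit conversion. Ties in peak height break
toward higher intensity; grayscale inputs are promoted to three channels
and 16-bit inputs rescaled, both with a recorded warning.

## Known limitations

* Microsteatosis and macrosteatosis are not distinguished; the score
  mixes both.
* The adaptive threshold requires a bimodal histogram; fields of pure
  white (no tissue) are caught by the no-tissue guard, but fields of
  pure tissue rely on the single-peak fallback described above.
* The tissue denominator treats every rejected white region as
  non-tissue; sinusoidal white space that a pathologist might count as
  tissue area is excluded, which contributes to pixel scores running
  below visual estimates.
* Images are scored independently; there is no stitching, no whole-slide
  input, and no calibration of the pixel score onto pathologist scales
  (the per-rater OLS slopes in the agreement module are the raw material
  for such a calibration, which is left to the user).
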