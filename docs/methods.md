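# Methods

## Problem and scope

`neolungseg` implements a classical rule-based pipeline for segmenting the
lung fields on neonatal anteroposterior chest radiographs of infants with
respiratory distress syndrome (RDS), together with the machinery needed to
evaluate it and to analyse the accompanying before/after clinical
measurements:

1. a six-stage segmentation pipeline (threshold → dilation → small-object
   removal → ROI masking → closing → overlay);
2. confusion-matrix performance indicators with batch summaries;
3. paired-samples statistics for before/after gas-analysis parameters,
   including closed-form recomputation from printed summary moments;
4. a synthetic phantom generator emulating the five-level radiographic
   severity grading of RDS, so every stage is testable without patient data.

## Segmentation model

The input is an 8-bit grayscale radiograph `X` (M×N, intensities 0–255).
The stages, with the package defaults:

* **Binarization.** `Y(i,j) = 1` iff `X(i,j) > T` in the literal
  bright-foreground convention, or `X(i,j) <= T` with the default inverted
  polarity. Aerated lung is radiolucent (dark) while RDS opacification is
  bright, and the clinically interesting region during recovery is the
  re-aerated lung field, so the default `invert_polarity=True` selects the
  dark side of the threshold. `T` defaults to Otsu's threshold computed on
  the 256-bin histogram; the implementation returns the smallest integer
  maximising the between-class variance so that ties are deterministic. A
  fixed threshold mode is provided for reproducibility studies. Otsu is
  implemented directly (the contract requires an integer 8-bit threshold,
  smallest-tie break, and consistency with the strict `> T` comparison);
  `skimage.filters.threshold_otsu` is used as a cross-check oracle in a
  test, never as the implementation.
* **Dilation.** Binary dilation `Z = Y ⊕ B` with a disk of radius 3
  strengthens contours and bridges small interruptions. All morphology uses
  zero padding: out-of-frame cells read as background. Lungs on AP chest
  films keep clear of the frame border, so border effects do not arise in
  the intended regime.
* **Small-object removal.** Connected components of area `<= U` pixels are
  discarded (note the inclusive bound: a component of exactly `U` pixels is
  removed). `U` defaults to 0.1% of the frame area, a scale-invariant noise
  floor (66 px at 256², 1 049 px at 1024²). Connectivity defaults to
  8-neighbour, configurable to 4.
* **ROI mask.** The pulmonary region of interest `Q` is, by default, the
  union of the 2 largest remaining components — one per lung field — with
  area ties broken by the smaller label in row-major labeling order. An
  external mask PNG can be supplied instead, and must match the frame
  dimensions.
* **Masking and closing.** `X_mask = W · Q` elementwise, then morphological
  closing (dilation followed by erosion, both zero-padded) with a disk of
  radius 7 fills gaps and joins interrupted contours; the larger element
  reflects the coarser scale of contour closing versus gap bridging. The
  closed mask is re-intersected with `Q` so `closed ⊆ roi` holds even when
  closing dilates past the ROI boundary.
* **Visualization.** The product image `X · X_closed` retains original
  intensities inside the mask; the rendered overlay replicates `X` on three
  channels and alpha-blends the configured color (default red) at weight
  0.5 inside the mask, rounding half-up.

With zero padding on both closing passes, foreground within one structuring
element radius of the frame border can be eroded; closing is extensive and
idempotent away from the border, and the property tests exercise exactly
that regime.

## Evaluation metrics

From pixelwise TP/TN/FP/FN against an expert (or phantom ground-truth)
mask: sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, precision TP/(TP+FP), F-measure 2PS/(P+S), Dice
2TP/(2TP+FP+FN), Matthews correlation coefficient, Jaccard TP/(TP+FP+FN).
Two algebraic identities are enforced by property tests: Dice = 2J/(1+J)
and F-measure = Dice.

A binary segmenter has a single operating point, so the default reported
AUC is (sensitivity + specificity)/2, reproducible from the confusion
counts alone. When the grayscale source is available, `auc_sweep` builds
the full ROC by sweeping the binarization threshold over 0–255 inside the
ROI and integrating by the trapezoidal rule; this equals the normalized
Mann–Whitney statistic with ties counted ½, which an exhaustive pairwise
oracle verifies on toy images.

Any indicator with a zero denominator is *undefined* and returned as an
explicit `None`, never silently replaced by 0 or 1 — silent substitution
would bias batch summaries. Batch summaries report per-indicator mean and
sample SD (n−1 denominator; SD = 0 for a single image), excluding undefined
entries and logging the exclusion counts.

## Paired clinical statistics

Each monitored gas-analysis parameter (FiO2, pH, pCO2, pO2, HCO3, BE) has a
before-therapy and an after-therapy series over the same patients.

* **Descriptives**: range, min, max, mean, sample SD, and the adjusted
  Fisher–Pearson skewness `G1 = g1·sqrt(n(n−1))/(n−2)` with
  `SE = sqrt(6n(n−1)/((n−2)(n+1)(n+3)))` (the SPSS-style estimator). At
  n = 32 this SE is 0.41.
* **Pair correlation**: sample Pearson r on complete pairs with the
  two-tailed p from `t = r·sqrt((n−2)/(1−r²))` on n−2 df.
* **Paired t-test**: on differences `d = before − after` (this sign
  convention makes an oxygen-requirement drop positive and a pH rise
  negative). Algebraically a one-sample t-test of `d` against 0; the
  implementation is verified to agree with `scipy.stats.ttest_1samp` to
  1e−12. Missing data are handled by pairwise deletion per parameter, so
  degrees of freedom may differ across parameters. Constant differences
  (sd = 0) yield an undefined t and p rather than an arbitrary convention.
  P-values are kept at full precision internally; truncation to 3 d.p. is a
  rendering concern only.
* **Summary recomputation**: `paired_from_summary` recovers SE, t, the
  95% CI and p from a printed mean difference, SD and n alone, and applied
  to `paired_test`'s own moments reproduces its outputs exactly (a tested
  1e−12 identity).

## Phantom generator

The phantom emulates what the pipeline needs to see, not photorealism: two
rotated dark ellipses (radiolucent lung fields, default intensity 60) on a
brighter soft-tissue background (default 180) with a bright mediastinal
band, at 256×256 by default for desk-scale runs (scale is parameterized;
the geometry is specified in frame fractions). The ground-truth mask is the
exact ellipse union — about 24% of the frame, within the plausible 10–45%
band for neonatal AP films — and is invariant to the corruption grade.

Severity is modeled after the five-level radiographic grading of RDS:

| grade | haze | patchy/streaky opacities | bronchograms | intent |
|------:|-----:|-------------------------:|-------------:|:-------|
| 1 | 0.00 | 0 | 0 | fine granular speckle only |
| 2 | 0.25 | 8 | 0 | patchy and streaky opacities |
| 3 | 0.50 | 16 | 0 | denser opacities, fading boundaries |
| 4 | 0.75 | 24 | 5 | hazy fields, air bronchograms |
| 5 | 1.00 | 0 | 0 | diffuse opacification, "white lungs" |

Haze linearly pulls the lung-field intensity toward the background
(haze = 1 leaves a mean lung/background contrast below 10 levels);
granulation is Gaussian speckle (SD 6) inside the lungs; opacities are
bright elliptical blobs and elongated streaks stamped inside the lung
fields, sized so that the closing stage cannot simply repair them;
bronchograms are branching bright strokes over the mediastinum. A mild
global noise floor (SD 2) is added everywhere. Appearance defaults were
calibrated once to make segmentation difficulty monotone in grade — no
quantitative appearance values exist for the clinical grading — and the
resulting behavior mirrors the clinical report: grades 1–3 segment well
(median Dice 0.94–0.89), while the near-uniform grade-4/5 films defeat a
global threshold entirely (median Dice ≈ 0.46).

What the phantom does **not** model: rib and clavicle shadows, the cardiac
silhouette, rotation/inspiration variability, scatter, detector response,
or longitudinal image series per patient. Passing the phantom tests
therefore demonstrates the pipeline's correctness and its qualitative
failure mode under diffuse opacification, not clinical-grade accuracy on
real films; published per-image indicator values on real radiographs
cannot be reproduced without the (undeposited) study images and expert
masks.

The clinical sampler draws before/after pairs from a bivariate normal with
specified means, SDs and correlation — the paired t-test assumes
approximately normal differences, and the published moment structure (the
six parameters at n = 32, with the HCO3 pair missing two patients) ships as
`TABLE_PAIR_SPECS`. No attempt is made to match printed skewness values. At
the FiO2 moments the implied population t is 27.88/(13.38/√32) ≈ 11.8, and
1,000-replicate simulation recovers the published 11.82 within 0.5 (the
small upward bias of the t statistic's mean is expected at n = 32).

## Numerical choices and edge cases

* Intensities are validated to integer [0, 255]; RGB inputs are reduced by
  BT.601 luma (0.299, 0.587, 0.114) rounded half-up, since no grayscale
  conversion is specified for JPEG acquisitions. 8-bit depth is assumed.
* Masks are stored as 8-bit PNG {0, 255}; all outputs are PNG so round-trip
  tests are bit-exact (JPEG is accepted only as input).
* Otsu on a constant image raises — there is no defined threshold.
* An empty post-cleaning mask under the auto ROI policy yields an all-empty
  result from `segment` (the standalone `make_roi_mask` raises, since a
  caller asking for an ROI of an empty mask has no candidate region).
* Tie-breaks are deterministic everywhere: smallest Otsu threshold,
  row-major first label for equal-area ROI components.
* Seeds: phantoms and samplers take explicit integer seeds
  (`numpy.random.default_rng`); identical spec ⇒ bit-identical output.

## Known data inconsistencies handled

The published summary tables carry internal inconsistencies that the
defaults resolve as follows: the after-therapy FiO2 mean is taken as 26.09
(consistent with the paired difference 27.88 and the table's own minimum),
not 20.09; the after-therapy pCO2 SD is taken as 1.03 (consistent with the
difference SD 1.86 through the moment identity
`sd_d² = sd_b² + sd_a² − 2·r·sd_b·sd_a`), not 0.18. The printed skewness SE
of 0.42 at n = 32 differs from the standard formula's 0.41; the formula
value is used. Printed rows whose rounded inputs cannot reproduce their
printed derived columns at 2 d.p. are treated as rounding artifacts of the
source and are not asserted by the acceptance tests.

## Problem sizes used by the test and acceptance runs

Phantoms are evaluated at 256×256, ten seeds per grade; metric identities on
1,000 random confusion tables; morphology oracle equivalence on 50 random
12×12 masks; t-calibration over 1,000 replicates at n = 32 and CI coverage
over 2,000 replicates. These sizes are the package's chosen desk-scale
defaults and complete in seconds.
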