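# neolungseg

Rule-based lung-field segmentation for neonatal chest radiographs, built for
studying respiratory distress syndrome (RDS) in preterm infants, where
surfactant deficiency opacifies the lung fields and the degree of
re-aeration under therapy is followed on serial films. The package bundles:

* **`lungseg`** — the segmentation pipeline: global threshold (Otsu or
  fixed) → binary dilation → small-object removal → pulmonary ROI masking →
  morphological closing → colored overlay;
* **`seg_eval`** — confusion-matrix indicators (sensitivity, specificity,
  accuracy, precision, F-measure, Dice, MCC, Jaccard, AUC) with
  mean ± SD batch summaries;
* **`clinstats`** — paired before/after statistics for gas-analysis
  parameters (descriptives with skewness, Pearson pair correlation, paired
  samples t-test, and closed-form recomputation from printed summary
  moments);
* **`phantom`** — synthetic radiograph phantoms with exact ground-truth
  lung masks across the five-level RDS severity grading, plus a
  bivariate-normal sampler for paired clinical series;
* **`raster_io`** — PNG/JPEG reading, lossless PNG mask/overlay writing;
* a `neolungseg` command-line interface binding it all together.

## The method in brief

A radiograph `X ∈ {0..255}^{M×N}` is thresholded (`Y = [X ≤ T]` by default,
since aerated lung is radiolucent; `T` from Otsu's 256-bin criterion),
dilated with a disk(3) element (`Z = Y ⊕ B`), cleaned of components with
area ≤ U (default 0.1% of the frame), restricted to the pulmonary ROI `Q`
(union of the two largest components, one per lung), closed with a disk(7)
element, and rendered as `X · X_closed` with the lung field blended in
color. Accuracy against a ground-truth mask is scored from pixel counts,
e.g. Dice = 2TP/(2TP+FP+FN). Therapy effect on a clinical parameter is the
paired t-test on within-patient differences d = before − after:
t = d̄/(s_d/√n) on n−1 df with the 95% CI d̄ ± t₀.₉₇₅,ₙ₋₁·s_d/√n.

Two printed-formula quirks are deliberately not reproduced: the accuracy
denominator is the standard TP+TN+FP+FN and the Jaccard numerator is the
standard TP (intersection over union); the source prints typographically
corrupted variants of both.

## Worked example

```sh
neolungseg phantom --grade 1 --seed 0 --clinical --out demo/
neolungseg segment demo/image.png --out demo/seg/
neolungseg evaluate --gt demo/gt_mask.png --pred demo/seg/closed.png --out demo/eval/
neolungseg stats demo/clinical_pairs.csv --out demo/stats/
```

The segment step prints

```
threshold_used=84 closed_foreground=17592
```

meaning Otsu chose T = 84 and the final lung mask covers 17 592 pixels
(~27% of the 256² frame). `demo/eval/report.json` then contains the
indicators of that mask against the phantom's exact ground truth — Dice
0.94 here; grade-1 phantoms segment nearly perfectly, while grade-5
("white lungs") phantoms defeat a global threshold by construction. The
stats step prints one paired-t row per parameter, e.g. for FiO2 (n = 32
sampled pairs at the published moments):

```
name  n_pairs  mean_before  mean_after  mean_diff     t  df  p_two_tailed
FiO2       32       54.617      27.630     26.987 10.449  31         0.000
```

i.e. the simulated oxygen requirement drops by ~27 percentage points after
therapy, t ≈ 10.4 on 31 df.

In Python the same pipeline is three calls:

```python
from neolungseg import grade_default_spec, make_phantom, segment, evaluate_pair

sample = make_phantom(grade_default_spec(1, seed=0))
result = segment(sample.image)            # default SegConfig
report = evaluate_pair(sample.gt_mask, result.closed)
print(round(report.dice, 3))              # 0.939
```

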