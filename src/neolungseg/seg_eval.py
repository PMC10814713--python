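"""Segmentation performance evaluation.

Confusion-matrix construction against expert ground truth and the nine
standard indicators: sensitivity, specificity, accuracy, precision,
F-measure, Dice, Matthews correlation coefficient (MCC), Jaccard (IoU) and
AUC.  For a binary (non-probabilistic) segmenter the reported AUC is the
operating-point value (sensitivity + specificity)/2; a full threshold-sweep
ROC AUC is available through :func:`auc_sweep` when the grayscale source
image is supplied.

A metric whose denominator is zero is *undefined* and reported as ``None``,
never silently substituted by 0 or 1; batch summaries exclude undefined
entries per metric and record the exclusion counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np

from .raster_io import as_binary, as_gray

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "BatchMetricSummary",
    "METRIC_NAMES",
    "confusion_counts",
    "metric_report",
    "evaluate_pair",
    "auc_sweep",
    "summarize_batch",
]

logger = logging.getLogger("neolungseg.seg_eval")

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "f_measure",
    "dice",
    "mcc",
    "jaccard",
    "auc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The nine indicators; ``None`` marks an undefined (0/0) metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    precision: Optional[float]
    f_measure: Optional[float]
    dice: Optional[float]
    mcc: Optional[float]
    jaccard: Optional[float]
    auc: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class BatchMetricSummary:
    """Per-metric mean and sample SD over a set of reports (Table-style)."""

    means: dict[str, Optional[float]]
    sds: dict[str, Optional[float]]
    n_images: int
    n_excluded: dict[str, int]


def confusion_counts(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Pixelwise 2×2 confusion counts of *pred* against ground truth *gt*."""
    g = as_binary(gt).astype(bool)
    p = as_binary(pred).astype(bool)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    tp = int(np.count_nonzero(g & p))
    tn = int(np.count_nonzero(~g & ~p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def metric_report(c: ConfusionCounts) -> MetricReport:
    """Compute the nine indicators from confusion counts.

    Any indicator with a zero denominator is returned as ``None``.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, c.total)
    prec = _ratio(tp, tp + fp)
    if prec is None or sens is None or prec + sens == 0:
        f = None
    else:
        f = 2 * prec * sens / (prec + sens)
    dice = _ratio(2 * tp, 2 * tp + fp + fn)
    jac = _ratio(tp, tp + fp + fn)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    auc = (sens + spec) / 2 if sens is not None and spec is not None else None
    return MetricReport(
        sensitivity=sens, specificity=spec, accuracy=acc, precision=prec,
        f_measure=f, dice=dice, mcc=mcc, jaccard=jac, auc=auc,
    )


def evaluate_pair(gt: np.ndarray, pred: np.ndarray) -> MetricReport:
    """Confusion counts followed by the indicator report."""
    return metric_report(confusion_counts(gt, pred))


def auc_sweep(image: np.ndarray, gt: np.ndarray, roi: np.ndarray, invert: bool = True) -> float:
    """Threshold-sweep ROC AUC of the grayscale image against ground truth.

    The ROC is built by sweeping the binarization threshold T over 0..255
    inside the ROI (foreground ``<= T`` when *invert*, else ``> T``); the
    area is the trapezoidal rule over the 256 operating points plus the
    corners (0,0) and (1,1).  Equals the normalized Mann–Whitney statistic
    (ties counted 1/2) of the pixel intensities.
    """
    x = as_gray(image)
    g = as_binary(gt).astype(bool)
    r = as_binary(roi).astype(bool)
    if not (x.shape == g.shape == r.shape):
        raise ValueError("image, gt and roi must share dimensions")
    if not r.any():
        raise ValueError("ROI is empty")
    pos = x[g & r]
    neg = x[~g & r]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: ground truth within ROI is single-class")
    hp = np.bincount(pos, minlength=256).astype(np.float64)
    hn = np.bincount(neg, minlength=256).astype(np.float64)
    if invert:
        # foreground = intensity <= T: rates are cumulative from the dark end
        tpr = np.cumsum(hp) / pos.size
        fpr = np.cumsum(hn) / neg.size
    else:
        # foreground = intensity > T: rates are tail sums
        tpr = (pos.size - np.cumsum(hp)) / pos.size
        fpr = (neg.size - np.cumsum(hn)) / neg.size
    fpr = np.concatenate(([0.0], fpr, [1.0]))
    tpr = np.concatenate(([0.0], tpr, [1.0]))
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def summarize_batch(reports: Sequence[MetricReport]) -> BatchMetricSummary:
    """Mean and sample SD (n−1) per indicator across *reports*.

    Undefined entries are excluded per metric; exclusion counts are logged
    and returned.  SD is 0 when a metric has a single defined value.
    """
    if len(reports) == 0:
        raise ValueError("at least one report is required")
    means: dict[str, Optional[float]] = {}
    sds: dict[str, Optional[float]] = {}
    excluded: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = np.array([v for r in reports if (v := getattr(r, name)) is not None], dtype=float)
        excluded[name] = len(reports) - vals.size
        if excluded[name]:
            logger.info("metric=%s excluded=%d of %d (undefined)", name, excluded[name], len(reports))
        if vals.size == 0:
            means[name] = None
            sds[name] = None
        else:
            means[name] = float(vals.mean())
            sds[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return BatchMetricSummary(means=means, sds=sds, n_images=len(reports), n_excluded=excluded)
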