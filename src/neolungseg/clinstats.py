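"""Paired clinical statistics for before/after gas-analysis measurements.

Implements the descriptive and inferential machinery used to assess
surfactant + inhaled-corticosteroid therapy in neonates with respiratory
distress syndrome:

* descriptive rows (range, min, max, mean ± SD, adjusted Fisher–Pearson
  skewness G1 with its standard error) per monitored parameter;
* Pearson correlation between before/after pairs with a two-tailed p-value;
* the paired samples t-test on within-subject differences d = before − after
  (algebraically a one-sample t-test of d against 0), with 95% CI;
* closed-form recomputation of the derived t-test columns (SE, CI, t, p)
  from printed summary moments (mean difference, SD, n) alone.

Missing values are handled by pairwise deletion per parameter: a subject is
dropped from a pair analysis only when either side of *that* pair is
missing, so degrees of freedom may differ across parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NumericSeries",
    "DescriptiveRow",
    "PairedResult",
    "SummaryInput",
    "SummaryResult",
    "describe",
    "pearson_pair",
    "paired_test",
    "paired_from_summary",
    "paired_table_from_frame",
]


@dataclass(frozen=True)
class NumericSeries:
    """A named measurement series; ``nan`` marks a missing value."""

    name: str
    values: np.ndarray
    unit: str = ""

    @classmethod
    def from_values(cls, name: str, values: Sequence[float], unit: str = "") -> "NumericSeries":
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("series values must be one-dimensional")
        return cls(name=name, values=arr, unit=unit)


def _series_values(series) -> np.ndarray:
    if isinstance(series, NumericSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


@dataclass(frozen=True)
class DescriptiveRow:
    name: str
    n: int
    range: float
    min: float
    max: float
    mean: float
    sd: float
    skewness: Optional[float]
    se_skewness: float


@dataclass(frozen=True)
class PairedResult:
    """All columns of a paired-samples t-test row."""

    name: str
    n_pairs: int
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    r: float
    r_pvalue: float
    mean_diff: float
    sd_diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    t: Optional[float]
    df: int
    p_two_tailed: Optional[float]


@dataclass(frozen=True)
class SummaryInput:
    """Printed summary moments of a difference column."""

    mean_diff: float
    sd_diff: float
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd_diff <= 0:
            raise ValueError("sd_diff must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SummaryResult:
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    df: int


def describe(series) -> DescriptiveRow:
    """Descriptive row: range/min/max, mean ± sample SD, skewness G1 ± SE.

    Skewness is the adjusted Fisher–Pearson estimator
    G1 = g1·sqrt(n(n−1))/(n−2) with SE = sqrt(6n(n−1)/((n−2)(n+1)(n+3)));
    it is undefined (``None``) for a constant series.  Requires at least
    three non-missing values.
    """
    name = series.name if isinstance(series, NumericSeries) else ""
    x = _series_values(series)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("series has no non-missing values")
    if x.size < 3:
        raise ValueError("descriptive skewness needs at least 3 values")
    n = int(x.size)
    sd = float(x.std(ddof=1))
    skew = float(stats.skew(x, bias=False)) if sd > 0 else None
    se_skew = float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))
    return DescriptiveRow(
        name=name, n=n,
        range=float(x.max() - x.min()), min=float(x.min()), max=float(x.max()),
        mean=float(x.mean()), sd=sd, skewness=skew, se_skewness=se_skew,
    )


def _complete_pairs(before, after) -> tuple[np.ndarray, np.ndarray]:
    b = _series_values(before)
    a = _series_values(after)
    if b.shape != a.shape:
        raise ValueError("before and after series must be aligned (same length)")
    keep = ~(np.isnan(b) | np.isnan(a))
    return b[keep], a[keep]


def pearson_pair(before, after) -> tuple[float, float]:
    """Sample Pearson r on complete pairs, with two-tailed p on n−2 df."""
    b, a = _complete_pairs(before, after)
    if b.size < 3:
        raise ValueError("Pearson correlation needs at least 3 complete pairs")
    if b.std(ddof=1) == 0 or a.std(ddof=1) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    res = stats.pearsonr(b, a)
    return float(res.statistic), float(res.pvalue)


def paired_test(before, after, alpha: float = 0.05, name: str = "") -> PairedResult:
    """Paired samples t-test on differences d = before − after.

    Pairwise deletion drops subjects missing either measurement.  The test
    equals a one-sample t-test of d against 0; the CI is
    mean_d ± t(1−alpha/2, n−1)·SE.  When the differences are constant
    (sd_diff = 0) the t statistic and p-value are undefined (``None``).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    b, a = _complete_pairs(before, after)
    n = int(b.size)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    if b.std(ddof=1) > 0 and a.std(ddof=1) > 0:
        r, r_p = pearson_pair(b, a) if n >= 3 else (float("nan"), float("nan"))
    else:
        r, r_p = float("nan"), float("nan")
    d = b - a
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0:
        se = 0.0
        t_stat = None
        p = None
        ci_low = ci_high = mean_d
    else:
        se = sd_d / np.sqrt(n)
        t_stat = mean_d / se
        p = float(2 * stats.t.sf(abs(t_stat), df))
        tc = stats.t.ppf(1 - alpha / 2, df)
        ci_low, ci_high = mean_d - tc * se, mean_d + tc * se
    return PairedResult(
        name=name or getattr(before, "name", ""), n_pairs=n,
        mean_before=float(b.mean()), sd_before=float(b.std(ddof=1)),
        mean_after=float(a.mean()), sd_after=float(a.std(ddof=1)),
        r=r, r_pvalue=r_p,
        mean_diff=mean_d, sd_diff=sd_d, se_diff=float(se),
        ci_low=float(ci_low), ci_high=float(ci_high),
        t=None if t_stat is None else float(t_stat), df=df,
        p_two_tailed=p,
    )


def paired_from_summary(s: SummaryInput) -> SummaryResult:
    """Recompute SE, 95% CI, t and two-tailed p from printed moments.

    Applied to a :func:`paired_test` result's own mean_diff/sd_diff/n this
    reproduces its se/ci/t/p exactly.
    """
    se = s.sd_diff / np.sqrt(s.n)
    t_stat = s.mean_diff / se
    df = s.n - 1
    tc = stats.t.ppf(1 - s.alpha / 2, df)
    p = float(2 * stats.t.sf(abs(t_stat), df))
    return SummaryResult(
        se=float(se),
        ci_low=float(s.mean_diff - tc * se),
        ci_high=float(s.mean_diff + tc * se),
        t=float(t_stat),
        p=p,
        df=df,
    )


def paired_table_from_frame(frame: pd.DataFrame, alpha: float = 0.05) -> list[PairedResult]:
    """Run paired tests on every ``<param>_before``/``<param>_after`` column
    pair of a patient table (one row per patient; blank cells = missing)."""
    params = sorted(
        c[: -len("_before")] for c in frame.columns if c.endswith("_before")
        if c[: -len("_before")] + "_after" in frame.columns
    )
    if not params:
        raise ValueError("no <param>_before/<param>_after column pairs found")
    return [
        paired_test(frame[f"{p}_before"].to_numpy(dtype=float),
                    frame[f"{p}_after"].to_numpy(dtype=float),
                    alpha=alpha, name=p)
        for p in params
    ]
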