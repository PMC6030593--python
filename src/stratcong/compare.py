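"""Cross-dataset comparison of tree-search methods.

Once per-dataset, per-method metric means exist, two methods are compared
with a paired Wilcoxon signed-rank test on the per-dataset differences
(method A mean − method B mean).  The repeated-measures structure of the
underlying meta-analysis collapses to this pairing once means are taken per
dataset; the per-dataset difference table is part of the result so richer
models can be fitted elsewhere.

The slope diagnostic regresses method B's per-dataset means on method A's
and tests the ordinary-least-squares slope against 1: a slope below 1 means
the methods diverge most on the datasets where congruence is highest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datasets import TreeSetSummary
from .metrics import METRIC_NAMES

__all__ = ["ComparisonResult", "SlopeTestResult", "paired_compare", "slope_test"]

#: largest sample for which the signed-rank null distribution is enumerated
#: exactly; above this the normal approximation with tie correction is used
EXACT_WILCOXON_MAX_N = 25


@dataclass
class ComparisonResult:
    metric: str
    dataset_ids: list[str]
    differences: list[float]  # method A mean − method B mean, per dataset
    mean_difference: float
    statistic: float
    p_value: float
    n_used: int
    n_supplied: int
    test_method: str  # "exact" | "approx" | "all-zero"

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "mean_difference": self.mean_difference,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "n_supplied": self.n_supplied,
            "test_method": self.test_method,
        }


def paired_compare(
    summaries_a: Sequence[TreeSetSummary],
    summaries_b: Sequence[TreeSetSummary],
    metric: str,
) -> ComparisonResult:
    """Paired per-dataset comparison of one metric between two methods.

    Summaries are matched by ``dataset_id``; datasets where either side's
    mean is undefined are dropped (the drop is visible via ``n_used`` versus
    ``n_supplied``).  The two-sided signed-rank p-value is exact for up to
    25 usable pairs (zero differences dropped, the standard signed-rank
    convention); larger samples use the normal approximation with tie
    correction.  All differences equal to zero yield p = 1.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    by_a = {s.dataset_id: s for s in summaries_a}
    by_b = {s.dataset_id: s for s in summaries_b}
    shared = [d for d in by_a if d in by_b]
    n_supplied = len(shared)
    ids, diffs = [], []
    for d in sorted(shared):
        va = by_a[d].mean(metric)
        vb = by_b[d].mean(metric)
        if va is None or vb is None:
            continue
        ids.append(d)
        diffs.append(va - vb)
    if len(diffs) < 2:
        raise ValueError(
            f"metric {metric!r}: need >= 2 usable dataset pairs, got {len(diffs)}"
        )
    arr = np.asarray(diffs, dtype=float)
    mean_diff = float(arr.mean())
    nonzero = arr[arr != 0.0]
    if nonzero.size == 0:
        stat, p, method = 0.0, 1.0, "all-zero"
    else:
        use_exact = nonzero.size <= EXACT_WILCOXON_MAX_N
        res = stats.wilcoxon(
            nonzero,
            zero_method="wilcox",
            alternative="two-sided",
            method="exact" if use_exact else "approx",
        )
        stat, p = float(res.statistic), float(res.pvalue)
        method = "exact" if use_exact else "approx"
    return ComparisonResult(
        metric=metric,
        dataset_ids=ids,
        differences=diffs,
        mean_difference=mean_diff,
        statistic=stat,
        p_value=min(p, 1.0),
        n_used=len(diffs),
        n_supplied=n_supplied,
        test_method=method,
    )


@dataclass
class SlopeTestResult:
    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_two_sided: float
    p_one_sided_less: float  # alternative: slope < null_slope
    n: int
    null_slope: float
    degenerate: bool  # perfect fit: zero residual variance

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "t_statistic": self.t_statistic,
            "p_two_sided": self.p_two_sided,
            "p_one_sided_less": self.p_one_sided_less,
            "n": self.n,
            "null_slope": self.null_slope,
            "degenerate": self.degenerate,
        }


def slope_test(
    x: Sequence[float], y: Sequence[float], null_slope: float = 1.0
) -> SlopeTestResult:
    """OLS of y on x with a t-test of the slope against ``null_slope``.

    ``t = (slope − null_slope) / SE`` on n − 2 degrees of freedom; both the
    two-sided and the one-sided (slope < null) p-value are reported.  A
    perfect fit (zero residual variance) makes the t statistic 0/0; such
    degenerate fits are flagged and given p = 1 if the slope equals the null
    exactly, else p = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    n = xa.size
    if n < 3:
        raise ValueError(f"need n >= 3 points, got {n}")
    sxx = float(np.sum((xa - xa.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("zero variance in x: slope undefined")
    slope = float(np.sum((xa - xa.mean()) * (ya - ya.mean())) / sxx)
    intercept = float(ya.mean() - slope * xa.mean())
    resid = ya - (intercept + slope * xa)
    sse = float(np.sum(resid**2))
    syy = float(np.sum((ya - ya.mean()) ** 2))
    df = n - 2
    # treat fits whose residuals are numerically zero as degenerate
    if sse <= 1e-12 * max(syy, 1.0):
        exact_null = math.isclose(slope, null_slope, rel_tol=1e-12, abs_tol=1e-12)
        p = 1.0 if exact_null else 0.0
        t_stat = 0.0 if exact_null else math.copysign(math.inf, slope - null_slope)
        one_sided = 1.0 if exact_null else (0.0 if slope < null_slope else 1.0)
        return SlopeTestResult(
            slope=slope, intercept=intercept, slope_se=0.0,
            t_statistic=t_stat, p_two_sided=p, p_one_sided_less=one_sided,
            n=n, null_slope=null_slope, degenerate=True,
        )
    se = math.sqrt(sse / df / sxx)
    t_stat = (slope - null_slope) / se
    p_two = float(2.0 * stats.t.sf(abs(t_stat), df))
    p_less = float(stats.t.cdf(t_stat, df))
    return SlopeTestResult(
        slope=slope, intercept=intercept, slope_se=se,
        t_statistic=t_stat, p_two_sided=p_two, p_one_sided_less=p_less,
        n=n, null_slope=null_slope, degenerate=False,
    )
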