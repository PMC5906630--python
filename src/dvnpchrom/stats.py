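"""Statistical primitives: Welch's t-test and box-plot summaries.

welch_t is authored directly from the textbook formulas (unequal-variance
t with Welch–Satterthwaite degrees of freedom) so it can be cross-checked
against an independent implementation in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(a, b) -> WelchResult:
    """Two-sided Welch's t-test (unequal variances).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), df by
    Welch–Satterthwaite, p from Student's t. Each sample needs n >= 2 and
    at least one nonzero variance; two identical degenerate samples give
    t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("welch_t requires n >= 2 in each sample")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        raise ValueError("welch_t undefined: zero variance in both samples "
                         "with unequal means")
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number box-plot summary with notches.

    Quartiles follow the Tukey hinge (midpoint) rule; whiskers reach the
    most extreme data within 1.5*IQR of the box; notches are
    median +/- notch_constant*IQR/sqrt(n), approximating a 95% CI of the
    median.
    """

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    notch_lo: float
    notch_hi: float
    n: int


def _hinges(sorted_values: np.ndarray) -> tuple[float, float]:
    """Tukey hinges: medians of the lower/upper half, each half including
    the overall median when n is odd."""
    n = len(sorted_values)
    half = (n + 1) // 2
    lower = sorted_values[:half]
    upper = sorted_values[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def boxplot_stats(values, notch_constant: float = 1.58,
                  whisker_factor: float = 1.5) -> BoxplotSummary:
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("boxplot_stats requires n >= 1")
    med = float(np.median(v))
    q1, q3 = _hinges(v)
    iqr = q3 - q1
    lo_fence = q1 - whisker_factor * iqr
    hi_fence = q3 + whisker_factor * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_lo = float(inside[0])
    whisker_hi = float(inside[-1])
    half = notch_constant * iqr / np.sqrt(len(v))
    return BoxplotSummary(
        median=med, q1=q1, q3=q3,
        whisker_lo=whisker_lo, whisker_hi=whisker_hi,
        notch_lo=med - half, notch_hi=med + half, n=len(v),
    )


def chi2_contingency_closed_2x2(a: float, b: float, c: float, d: float) -> float:
    """Closed-form 2x2 chi-square without continuity correction:
    n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)). Used as an independent oracle."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("degenerate 2x2 table")
    return n * (a * d - b * c) ** 2 / denom
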