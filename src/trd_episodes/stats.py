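"""Inferential machinery for group comparisons.

Two-sample t-tests from summary statistics (pooled or Welch-Satterthwaite
degrees of freedom, with an optional preliminary F-test choosing between
them), the large-sample two-proportion z-test with pooled standard error,
and the Bonferroni multiple-comparison cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _st


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float | None
    p_value: float
    method: str  # pooled_t | satterthwaite_t | two_proportion_z


def _f_test_equal_variances(sd1, n1, sd2, n2) -> float:
    """Two-tailed p of the folded F-test of equal variances."""
    v1, v2 = sd1 ** 2, sd2 ** 2
    if v1 == v2:
        return 1.0
    if v1 >= v2:
        f, dfn, dfd = (v1 / v2 if v2 > 0 else math.inf), n1 - 1, n2 - 1
    else:
        f, dfn, dfd = (v2 / v1 if v1 > 0 else math.inf), n2 - 1, n1 - 1
    return min(1.0, 2.0 * _st.f.sf(f, dfn, dfd))


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variance_rule: str = "auto",
) -> TestResult:
    """Two-tailed two-sample t-test from summary statistics.

    variance_rule: "pooled" uses the pooled variance with n1+n2-2 df;
    "satterthwaite" uses the Welch statistic with Welch-Satterthwaite df;
    "auto" picks pooled iff a preliminary F-test of equal variances is
    non-significant at the 5% level. With zero variance in both groups
    and equal means, p = 1 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if variance_rule not in ("pooled", "satterthwaite", "auto"):
        raise ValueError(f"unknown variance_rule {variance_rule!r}")

    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, "pooled_t")
        return TestResult(math.inf if mean1 > mean2 else -math.inf,
                          float(n1 + n2 - 2), 0.0, "pooled_t")

    if variance_rule == "auto":
        variance_rule = (
            "pooled" if _f_test_equal_variances(sd1, n1, sd2, n2) > 0.05
            else "satterthwaite"
        )

    v1, v2 = sd1 ** 2, sd2 ** 2
    if variance_rule == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
        method = "pooled_t"
    else:
        a, b = v1 / n1, v2 / n2
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
        method = "satterthwaite_t"
    t = (mean1 - mean2) / se
    p = 2.0 * _st.t.sf(abs(t), df)
    return TestResult(t, df, min(1.0, p), method)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Large-sample two-proportion z-test with pooled standard error,
    two-tailed, without continuity correction."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return TestResult(0.0, None, 1.0, "two_proportion_z")
    z = (p1 - p2) / se
    p = 2.0 * _st.norm.sf(abs(z))
    return TestResult(z, None, min(1.0, p), "two_proportion_z")


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance cutoff alpha / n."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons
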