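"""Statistical battery: normality-gated location tests with Bonferroni
correction, RSS aberration summaries, biomarker regressions, and paired
device-compatibility comparisons.

Coefficient distributions across eyes are frequently skewed, so every
location test is gated on a Shapiro-Wilk normality check: a parametric
t-test when normality is not rejected, a Wilcoxon signed-rank test when it
is.  The family for Bonferroni correction defaults to the four
single-angular-frequency Zernike terms (Y-tilt, X-tilt, Y-coma, X-coma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .zernike import CoefficientVector, ansi_indices

__all__ = [
    "TestResult",
    "RegressionResult",
    "gated_one_sample_test",
    "gated_paired_test",
    "rss_astigmatism",
    "rss_hoa_excluding_coma",
    "biomarker_regression",
    "device_compatibility",
]

DEFAULT_FAMILY_SIZE = 4  # the single-angular-frequency quartet


@dataclass(frozen=True)
class TestResult:
    term: str
    test_name: str  # one-sample t | wilcoxon | paired t | paired wilcoxon | degenerate
    statistic: float
    p_raw: float
    p_adjusted: float
    shapiro_p: float
    n: int

    def __post_init__(self) -> None:
        if self.p_adjusted + 1e-15 < self.p_raw:
            raise ValueError("adjusted p cannot fall below the raw p")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


def _bonferroni(p: float, family_size: int) -> float:
    return min(1.0, p * family_size)


def gated_one_sample_test(
    values,
    term: str = "",
    alpha_normality: float = 0.05,
    family_size: int = DEFAULT_FAMILY_SIZE,
) -> TestResult:
    """Test whether a coefficient's cohort location differs from zero.

    Shapiro-Wilk at ``alpha_normality`` selects the branch: one-sample t-test
    when normality passes, Wilcoxon signed-rank against median zero when it
    fails.  Both the raw and Bonferroni-adjusted p are reported.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3 for term {term!r}, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError(
            f"all {x.size} values for term {term!r} are identical; the "
            "normality test is undefined"
        )
    sw = sps.shapiro(x)
    if sw.pvalue >= alpha_normality:
        res = sps.ttest_1samp(x, 0.0)
        name = "one-sample t"
    else:
        res = sps.wilcoxon(x)
        name = "wilcoxon"
    return TestResult(
        term=term,
        test_name=name,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=_bonferroni(float(res.pvalue), family_size),
        shapiro_p=float(sw.pvalue),
        n=int(x.size),
    )


def gated_paired_test(
    a,
    b,
    term: str = "",
    alpha_normality: float = 0.05,
    family_size: int = 1,
) -> TestResult:
    """Paired comparison of two matched samples via the normality-gated test.

    All-zero differences (byte-identical measurements) are reported as a
    degenerate result with p = 1 rather than an error, since they carry the
    strongest possible evidence of compatibility.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.allclose(d, 0.0):
        return TestResult(term=term, test_name="degenerate", statistic=0.0,
                          p_raw=1.0, p_adjusted=1.0, shapiro_p=1.0, n=int(d.size))
    if np.ptp(d) == 0:
        raise ValueError(f"paired differences for {term!r} are a nonzero constant")
    sw = sps.shapiro(d)
    if sw.pvalue >= alpha_normality:
        res = sps.ttest_rel(a, b)
        name = "paired t"
    else:
        res = sps.wilcoxon(d)
        name = "paired wilcoxon"
    return TestResult(
        term=term,
        test_name=name,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=_bonferroni(float(res.pvalue), family_size),
        shapiro_p=float(sw.pvalue),
        n=int(d.size),
    )


def rss_astigmatism(coeffs: CoefficientVector) -> float:
    """Root-sum-square of the primary astigmatism pair Z(2,-2), Z(2,2), in um."""
    return float(np.hypot(coeffs.coefficient(2, -2), coeffs.coefficient(2, 2)))


def rss_hoa_excluding_coma(coeffs: CoefficientVector) -> float:
    """RSS of higher-order terms (n in 3..5) excluding primary coma Z(3,+/-1), um."""
    total = 0.0
    for idx in ansi_indices(coeffs.max_order):
        if idx.n >= 3 and not (idx.n == 3 and abs(idx.m) == 1):
            total += coeffs.coeffs[idx.j] ** 2
    return float(np.sqrt(total))


def biomarker_regression(x, y) -> RegressionResult:
    """OLS regression of y on x with Pearson correlation.

    Used for lid-wiper coma (um) on lid-wiper gradient (um/mm), so the slope
    carries units of mm; also for the RSS aberration partners.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def device_compatibility(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    terms: list[int] | None = None,
    alpha_normality: float = 0.05,
    alpha: float = 0.05,
) -> tuple[list[TestResult], bool]:
    """Per-term paired comparison of coefficient tables from two devices.

    Tables are keyed by (subject_id, eye); unmatched keys raise.  Returns the
    per-term results and a pooling decision: poolable iff no term's raw p
    falls below ``alpha``.
    """
    if terms is None:
        terms = [idx.j for idx in ansi_indices(5)]
    key_cols = ["subject_id", "eye"]
    a = table_a.set_index(key_cols).sort_index()
    b = table_b.set_index(key_cols).sort_index()
    missing_in_b = sorted(set(a.index) - set(b.index))
    missing_in_a = sorted(set(b.index) - set(a.index))
    if missing_in_a or missing_in_b:
        raise ValueError(
            "unmatched pairs between device tables: "
            f"missing in A={missing_in_a}, missing in B={missing_in_b}"
        )
    b = b.loc[a.index]
    results = []
    for j in terms:
        col = f"c_j{j}"
        results.append(
            gated_paired_test(
                a[col].to_numpy(), b[col].to_numpy(),
                term=col, alpha_normality=alpha_normality,
                family_size=1,
            )
        )
    poolable = all(r.p_raw >= alpha for r in results)
    return results, poolable
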