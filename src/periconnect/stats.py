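"""Cohort statistics for connected/unconnected cortical ratios.

Cross-sectional: ratios are tested against 1 with a one-sample t test, gated
by Shapiro-Wilk normality (the non-normal branch uses the Wilcoxon
signed-rank test against 1); three-group comparisons use ANOVA or its
Kruskal-Wallis equivalent with pairwise mean differences +/- SE; associations
with cognition use ordinary least squares adjusted for age, education and
WMH volume; families of p-values are corrected with the Benjamini-Hochberg
step-up procedure.

Longitudinal: baseline ratio and MMSE are z-standardized with their baseline
mean and SD, the same anchors standardize the 12-month values; the
two-timepoint repeated-measures comparison reduces to a paired t test
(F = t^2), and the measure-by-time interaction of the mixed model comparing
the two slopes reduces to a one-sample test of the per-subject difference of
standardized changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TestResult",
    "one_sample_vs_unity",
    "group_compare",
    "adjusted_regression",
    "bh_adjust",
    "standardize_longitudinal",
    "paired_change_test",
    "slope_comparison",
]

NORMALITY_ALPHA = 0.05


@dataclass
class TestResult:
    label: str
    n: int
    estimate: float
    se: float
    statistic: float
    p: float
    method: str
    normality_p: float | None = None
    p_adjusted: float | None = None
    degenerate: bool = False
    extra: dict | None = None


def _shapiro_p(x: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0:
        return float("nan")
    return float(sps.shapiro(x).pvalue)


def one_sample_vs_unity(ratios, label: str = "ratio", null_value: float = 1.0) -> TestResult:
    """Test whether the mean ratio differs from 1 (normality-gated).

    Shapiro-Wilk p >= 0.05 -> one-sample t test; otherwise Wilcoxon
    signed-rank against the null value. Two-tailed throughout.
    """
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 ratios, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / math.sqrt(n)
    if np.ptp(x) == 0:
        # all values identical: the t statistic is undefined
        p = 1.0 if mean == null_value else float("nan")
        return TestResult(label, n, mean, 0.0, float("nan"), p,
                          method="degenerate", normality_p=float("nan"), degenerate=True)
    norm_p = _shapiro_p(x)
    if np.isnan(norm_p) or norm_p >= NORMALITY_ALPHA:
        t, p = sps.ttest_1samp(x, null_value)
        return TestResult(label, n, mean, se, float(t), float(p),
                          method="t", normality_p=norm_p)
    stat, p = sps.wilcoxon(x - null_value)
    return TestResult(label, n, mean, se, float(stat), float(p),
                      method="wilcoxon", normality_p=norm_p)


def group_compare(values, groups, label: str = "ratio") -> tuple[TestResult, pd.DataFrame]:
    """Three-group comparison with pairwise mean differences +/- SE.

    ANOVA when every group passes Shapiro-Wilk at 0.05, otherwise
    Kruskal-Wallis.  Pairwise contrasts report mean difference, pooled SE and
    an uncorrected two-sample p (t or Mann-Whitney to match the gate).
    Groups with fewer than 2 observations are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    by_group: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        xg = values[groups == g]
        if len(xg) < 2:
            warnings.warn(f"group {g} has n={len(xg)} < 2; dropped", RuntimeWarning)
            continue
        by_group[str(g)] = xg
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    samples = list(by_group.values())
    norm_ps = [_shapiro_p(x) for x in samples]
    normal = all(np.isnan(p) or p >= NORMALITY_ALPHA for p in norm_ps)
    if all(np.ptp(x) == 0 for x in samples):
        stat, p, method = float("nan"), float("nan"), "degenerate"
    elif normal:
        stat, p = sps.f_oneway(*samples)
        method = "anova"
    else:
        stat, p = sps.kruskal(*samples)
        method = "kruskal"
    n = int(sum(len(x) for x in samples))
    grand = float(values.mean())
    overall = TestResult(label, n, grand, float("nan"), float(stat), float(p),
                         method=method, normality_p=float(min(norm_ps)),
                         degenerate=method == "degenerate")

    rows = []
    for (ga, xa), (gb, xb) in combinations(by_group.items(), 2):
        diff = float(xa.mean() - xb.mean())
        va = xa.var(ddof=1) / len(xa)
        vb = xb.var(ddof=1) / len(xb)
        se = math.sqrt(va + vb)
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            pp = 1.0 if diff == 0 else float("nan")
        elif normal:
            pp = float(sps.ttest_ind(xa, xb, equal_var=True).pvalue)
        else:
            pp = float(sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        rows.append({"group_a": ga, "group_b": gb, "mean_difference": diff,
                     "se": se, "p": pp, "n_a": len(xa), "n_b": len(xb)})
    return overall, pd.DataFrame(rows)


def adjusted_regression(
    table: pd.DataFrame,
    score_col: str,
    ratio_col: str,
    covariates=("age", "education_yrs", "wmh_volume_ml"),
    subgroup: pd.Series | None = None,
    label: str | None = None,
) -> TestResult:
    """OLS of a cognitive score on a ratio, adjusted for the covariates.

    Returns the ratio coefficient with SE and two-tailed p. A rank-deficient
    design is flagged degenerate and no coefficient is reported.
    """
    df = table if subgroup is None else table.loc[np.asarray(subgroup, dtype=bool)]
    cols = [score_col, ratio_col, *covariates]
    df = df[cols].dropna()
    n = len(df)
    k = 1 + len(covariates)
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} predictors")
    exog = sm.add_constant(df[[ratio_col, *covariates]].to_numpy(dtype=float),
                           has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        return TestResult(label or ratio_col, n, float("nan"), float("nan"),
                          float("nan"), float("nan"), method="regression",
                          degenerate=True)
    fit = sm.OLS(df[score_col].to_numpy(dtype=float), exog).fit()
    return TestResult(
        label or ratio_col, n,
        estimate=float(fit.params[1]), se=float(fit.bse[1]),
        statistic=float(fit.tvalues[1]), p=float(fit.pvalues[1]),
        method="regression",
        extra={"r_squared": float(fit.rsquared)},
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``p_adj(i) = min_{j >= i} (m / j) * p(j)`` over the ascending sort,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def standardize_longitudinal(
    baseline: np.ndarray, month12: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Baseline-anchored z-scores: both timepoints use the baseline mean/SD."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(month12, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 baseline values")
    mean_b = float(b.mean())
    sd_b = float(b.std(ddof=1))
    if sd_b == 0:
        raise ValueError("baseline SD is zero; cannot standardize")
    return (b - mean_b) / sd_b, (f - mean_b) / sd_b, mean_b, sd_b


def paired_change_test(baseline, month12, label: str = "ratio") -> TestResult:
    """Two-timepoint repeated-measures comparison (paired t; F = t^2).

    Pairs with a missing value at either timepoint are dropped with a
    warning.  With zero variance of the change the result is flagged
    degenerate and only the mean change is reported.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(month12, dtype=float)
    if len(b) != len(f):
        raise ValueError("baseline and month-12 vectors must pair by subject")
    ok = np.isfinite(b) & np.isfinite(f)
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} unpaired subjects", RuntimeWarning)
    b, f = b[ok], f[ok]
    n = len(b)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = f - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        p = 1.0 if mean_d == 0 else float("nan")
        return TestResult(label, n, mean_d, 0.0, float("nan"), p,
                          method="paired", degenerate=True)
    t, p = sps.ttest_rel(f, b)
    return TestResult(label, n, mean_d, sd_d / math.sqrt(n), float(t), float(p),
                      method="paired")


def slope_comparison(
    z_ratio_baseline, z_ratio_m12, z_mmse_baseline, z_mmse_m12,
    label: str = "ratio_vs_mmse",
) -> TestResult:
    """Compare the standardized 12-month slopes of the ratio and of MMSE.

    With two timepoints the mixed-model measure-by-time interaction equals a
    one-sample test of ``d_i = dz_ratio_i - dz_mmse_i`` against 0.  Negative
    mean ``d`` means the ratio declines faster than cognition.
    """
    d = (np.asarray(z_ratio_m12, float) - np.asarray(z_ratio_baseline, float)) - (
        np.asarray(z_mmse_m12, float) - np.asarray(z_mmse_baseline, float)
    )
    ok = np.isfinite(d)
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} unpaired subjects", RuntimeWarning)
    d = d[ok]
    n = len(d)
    if n < 3:
        raise ValueError(f"need at least 3 paired subjects, got {n}")
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        p = 1.0 if mean_d == 0 else float("nan")
        return TestResult(label, n, mean_d, 0.0, float("nan"), p,
                          method="paired", degenerate=True)
    t, p = sps.ttest_1samp(d, 0.0)
    return TestResult(label, n, mean_d, sd_d / math.sqrt(n), float(t), float(p),
                      method="paired")
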