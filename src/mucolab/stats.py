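"""Cohort statistics: metabolic indices and the study's decision rules.

Group comparisons follow the rule used throughout the mucus panels: an
unpaired t test when both groups are normally distributed, a two-sided
Mann-Whitney U test otherwise.  Normality is judged with the
D'Agostino-Pearson omnibus test, which is undefined below n = 8; smaller
samples (common with 4-10 mice per group) default to the nonparametric
path.  Correlations are Pearson when both variables pass the normality
gate, Spearman otherwise, with a linear regression line reported only for
significant correlations.  HOMA-IR is the standard fasting
glucose-insulin product index.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "GroupComparison",
    "homa_ir",
    "insulin_ng_ml_to_uU_ml",
    "label_diabetic",
    "mann_whitney",
    "normality_test",
    "is_normal",
    "correlate",
    "compare_groups",
    "DIABETES_GLUCOSE_THRESHOLD_MM",
]

#: Postprandial blood glucose (mM) above which a NOD mouse counts as diabetic.
DIABETES_GLUCOSE_THRESHOLD_MM = 14.5

#: Exact Mann-Whitney enumeration is used up to this combined sample size.
_EXACT_MW_MAX_N = 14

#: Exact Spearman permutation p-values are enumerated up to this n.
_EXACT_SPEARMAN_MAX_N = 9


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int = 0
    note: str = ""


@dataclass
class CorrelationResult:
    method: str  # "pearson" or "spearman"
    coefficient: float
    p_value: float
    n: int
    x_normal: bool
    y_normal: bool
    slope: float | None = None  # regression line, only when significant
    intercept: float | None = None


@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, str]
    test: TestResult
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]


# ---------------------------------------------------------------------------
# Metabolic indices
# ---------------------------------------------------------------------------


def homa_ir(glucose_mM, insulin_uU_ml):
    """Homeostatic model assessment of insulin resistance.

    ``(fasting glucose [mM] × fasting insulin [µU/ml]) / 22.5``; exactly
    bilinear in its arguments.  Accepts scalars or arrays.
    """
    g = np.asarray(glucose_mM, dtype=float)
    i = np.asarray(insulin_uU_ml, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("glucose and insulin must be positive")
    out = g * i / 22.5
    return float(out) if out.ndim == 0 else out


def insulin_ng_ml_to_uU_ml(insulin_ng_ml, factor: float = 28.8):
    """Convert an insulin ELISA readout from ng/ml to µU/ml.

    The default factor (1 ng/ml ≈ 28.8 µU/ml) follows the WHO insulin
    standard; assay-specific factors can be substituted.
    """
    return np.asarray(insulin_ng_ml, dtype=float) * factor


def label_diabetic(postprandial_glucose_mM):
    """True when blood glucose strictly exceeds 14.5 mM."""
    g = np.asarray(postprandial_glucose_mM, dtype=float)
    if np.any(g <= 0):
        raise ValueError("glucose must be positive")
    out = g > DIABETES_GLUCOSE_THRESHOLD_MM
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The p-value comes from the exact null distribution (full enumeration of
    rank arrangements) when the combined sample size is at most 14 and the
    data are tie-free; otherwise from the tie-corrected normal
    approximation with continuity correction.  The ``method`` field records
    which path ran.  If every value in both groups is identical the test is
    uninformative and returns p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical; Mann-Whitney is uninformative")
        return TestResult(
            "mann-whitney (degenerate)", a.size * b.size / 2.0, 1.0, a.size, b.size,
            note="degenerate: all values identical",
        )
    ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size) <= _EXACT_MW_MAX_N and not ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    method = "mann-whitney (exact)" if exact else "mann-whitney (normal approx.)"
    return TestResult(method, float(res.statistic), float(res.pvalue), a.size, b.size)


def normality_test(x) -> TestResult:
    """D'Agostino-Pearson omnibus normality test (K², chi-square(2) p).

    Undefined below n = 8: such samples get an explicit "insufficient n"
    result (p = NaN) which downstream rules treat as not normal, as do
    zero-variance samples.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        return TestResult(
            "dagostino-pearson", float("nan"), float("nan"), x.size,
            note="insufficient n (< 8); treated as not normal",
        )
    if np.ptp(x) == 0:
        return TestResult(
            "dagostino-pearson", float("nan"), float("nan"), x.size,
            note="zero variance; treated as not normal",
        )
    stat, p = sps.normaltest(x)
    return TestResult("dagostino-pearson", float(stat), float(p), x.size)


def is_normal(x, alpha: float = 0.05) -> bool:
    """Normality gate: passes only when the omnibus test ran and p > alpha."""
    res = normality_test(x)
    return bool(np.isfinite(res.p_value) and res.p_value > alpha)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman's rho by full enumeration."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Normality-gated correlation with conditional regression line.

    Pearson when both variables pass the D'Agostino-Pearson gate, Spearman
    otherwise (p exact by permutation enumeration for n ≤ 9, t
    approximation above).  A least-squares regression line is attached only
    when the correlation is significant (p ≤ 0.05), mirroring the display
    convention that a regression line marks a significant correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a variable; correlation undefined")
    xn, yn = is_normal(x, alpha), is_normal(y, alpha)
    if xn and yn:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        method = "spearman"
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        r = float(sps.spearmanr(x, y).statistic)
        if x.size <= _EXACT_SPEARMAN_MAX_N:
            p = _exact_spearman_p(rx, ry, r)
        else:
            p = float(sps.spearmanr(x, y).pvalue)
    slope = intercept = None
    if p <= 0.05:
        fit = sps.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return CorrelationResult(method, float(r), float(p), x.size, xn, yn, slope, intercept)


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-group comparison with the normality-gated test choice.

    Dispatches to an unpaired t test when both groups pass the
    D'Agostino-Pearson gate, to the Mann-Whitney U test otherwise, and
    reports group means ± SD alongside.  Exactly two groups must be
    present.
    """
    labels = list(pd.unique(table[group_col]))
    if len(labels) != 2:
        raise ValueError(
            f"expected exactly two groups, found {len(labels)}; "
            "run pairwise comparisons instead"
        )
    a = np.asarray(table.loc[table[group_col] == labels[0], variable], dtype=float)
    b = np.asarray(table.loc[table[group_col] == labels[1], variable], dtype=float)
    if is_normal(a, alpha) and is_normal(b, alpha):
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            test = TestResult("t-test (degenerate)", 0.0, 1.0, a.size, b.size,
                              note="degenerate: all values identical")
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
            test = TestResult("unpaired t-test", float(stat), float(p), a.size, b.size)
    else:
        test = mann_whitney(a, b)
    return GroupComparison(
        variable=variable,
        groups=(str(labels[0]), str(labels[1])),
        test=test,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(a.size, b.size),
    )
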