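"""Group-statistics battery for the cohort analysis.

Covers the study's full inferential toolkit: a Shapiro-Wilk normality gate
routing group comparisons to Welch's t-test or the Mann-Whitney U test,
chi-square tests of frequency tables, interobserver ICC(2,1) with an
F-based confidence interval, Spearman rank correlation, age/sex-adjusted
multiple linear regression, and ROC analysis with a Youden-optimal cutoff.

Standard distributions and fits come from scipy / statsmodels; the pieces
with study-specific contracts (exact Mann-Whitney enumeration with ties,
ICC variance components, tie-corrected AUC and cutoff tie-breaking) are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ICCResult",
    "GroupComparison",
    "RegressionResult",
    "ROCResult",
    "icc_absolute",
    "compare_groups",
    "chi_square",
    "spearman",
    "ols_adjusted",
    "roc_analysis",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation: two-way random, single measures, absolute
    agreement (ICC(2,1)), with a 95% CI from the F-distribution method."""

    icc: float
    ci95: tuple[float, float]
    model: str = "ICC(2,1) two-way random, single measures, absolute agreement"
    degenerate: bool = False


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p: float
    test: str                      # "t" | "Mann-Whitney" | "chi-square"
    summary_a: str = ""
    summary_b: str = ""


@dataclass(frozen=True)
class PredictorEffect:
    name: str
    beta: float
    ci95: tuple[float, float]
    p: float


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    n: int
    effects: tuple[PredictorEffect, ...]

    def effect(self, name: str) -> PredictorEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class ROCResult:
    """ROC of a score where LOWER values indicate disease."""

    auc: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    orientation: str = "lower score = disease"


# --------------------------------------------------------------------------
# Interobserver agreement

def icc_absolute(readings: np.ndarray) -> ICCResult:
    """ICC(2,1) from two-way random-effects mean squares.

    `readings` is an (n_subjects, k_raters) matrix with no missing cells.
    """
    y = np.asarray(readings, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("readings must be subjects x raters (>= 2 raters)")
    n, k = y.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.isfinite(y).all():
        raise ValueError("missing or non-finite cells")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    sse = sst - ssb - ssc
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= 1e-15 * max(sst, 1.0):
        return ICCResult(icc=0.0, ci95=(0.0, 0.0), degenerate=True)
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong); Satterthwaite df for the column term.
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - ALPHA / 2, n - 1, v)
        f2 = stats.f.ppf(1 - ALPHA / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        lower = upper = 1.0
    lower = min(lower, icc)
    upper = max(upper, icc)
    return ICCResult(icc=float(icc), ci95=(float(lower), float(upper)))


# --------------------------------------------------------------------------
# Group comparisons

def _summary_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.3f} ({np.std(x, ddof=1):.3f})"


def _summary_median_range(x: np.ndarray) -> str:
    return f"{np.median(x):.3f} [{np.min(x):.3f}-{np.max(x):.3f}]"


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (ties allowed).

    Enumerates all C(n1+n2, n1) assignments of the pooled values to group A
    and compares each assignment's U (computed on midranks) against the
    observed U; two-sided p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    total = comb(n1 + n2, n1)
    le = ge = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(u_obs), p


def compare_groups(
    values_a: np.ndarray, values_b: np.ndarray, force_test: str | None = None
) -> GroupComparison:
    """Compare two independent samples with a normality-gated test choice.

    Both samples normal by Shapiro-Wilk (alpha 0.05) -> Welch's t-test;
    otherwise Mann-Whitney U (exact enumeration when both n <= 8, else the
    tie-corrected normal approximation). `force_test` ("t" | "mwu")
    bypasses the gate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")

    if force_test is None:
        normal = True
        for x in (a, b):
            if np.ptp(x) == 0:
                normal = False       # constant sample: Shapiro undefined
                break
            if stats.shapiro(x).pvalue < ALPHA:
                normal = False
                break
        test = "t" if normal else "mwu"
    else:
        test = force_test

    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(
            statistic=float(res.statistic),
            p=float(res.pvalue),
            test="t",
            summary_a=_summary_mean_sd(a),
            summary_b=_summary_mean_sd(b),
        )

    if len(a) <= 8 and len(b) <= 8:
        u, p = _mwu_exact(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        u, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        statistic=u,
        p=p,
        test="Mann-Whitney",
        summary_a=_summary_median_range(a),
        summary_b=_summary_median_range(b),
    )


def chi_square(table: np.ndarray) -> GroupComparison:
    """Pearson chi-square on a frequency table (no continuity correction)."""
    t = np.asarray(table)
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must hold nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(t, correction=False)
    return GroupComparison(statistic=float(res.statistic), p=float(res.pvalue),
                           test="chi-square")


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its
    t-approximation p-value on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Adjusted regression

def ols_adjusted(
    outcome: np.ndarray, predictors: dict[str, np.ndarray], outcome_label: str = "y"
) -> RegressionResult:
    """OLS of `outcome` on named predictors (intercept added), with t-based
    95% CIs and two-sided p-values per predictor."""
    y = np.asarray(outcome, dtype=float)
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        full = np.linalg.matrix_rank(design)
        collinear = [
            names[j]
            for j in range(len(names))
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == full
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=ALPHA)
    effects = tuple(
        PredictorEffect(
            name=names[j],
            beta=float(fit.params[j + 1]),
            ci95=(float(ci[j + 1, 0]), float(ci[j + 1, 1])),
            p=float(fit.pvalues[j + 1]),
        )
        for j in range(len(names))
    )
    return RegressionResult(outcome=outcome_label, n=len(y), effects=effects)


# --------------------------------------------------------------------------
# ROC

def roc_analysis(scores: np.ndarray, is_disease: np.ndarray) -> ROCResult:
    """ROC of a score oriented so lower values indicate disease.

    AUC is the tie-corrected Mann-Whitney estimator (concordant pairs count
    1, ties 1/2).  The cutoff maximises Youden's J = sens + spec - 1 over
    midpoints between adjacent observed scores; classification is
    score <= cutoff -> disease.  J-ties break toward higher sensitivity,
    then the lower cutoff.
    """
    s = np.asarray(scores, dtype=float)
    d = np.asarray(is_disease, dtype=bool)
    if len(s) != len(d):
        raise ValueError("scores and labels differ in length")
    pos = s[d]
    neg = s[~d]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    diff = pos[:, None] - neg[None, :]
    auc = float(((diff < 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)

    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0], uniq]
    )
    best = None
    for c in np.sort(candidates):
        sens = float((pos <= c).mean())
        spec = float((neg > c).mean())
        j = sens + spec - 1.0
        key = (round(j, 12), round(sens, 12), -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    return ROCResult(
        auc=auc,
        cutoff=float(cutoff),
        sensitivity_pct=100.0 * sens,
        specificity_pct=100.0 * spec,
    )
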