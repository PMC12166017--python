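from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from alps_glymph import (
    chi_square,
    compare_groups,
    icc_absolute,
    ols_adjusted,
    roc_analysis,
    spearman,
)


# --------------------------------------------------------------------------
# ICC

def icc_oracle(y):
    """Variance-components oracle: explicit two-way ANOVA sums on loops."""
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = (sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
           - (n - 1) * msr - (k - 1) * msc)
    mse = sse / ((n - 1) * (k - 1))
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc3 = (msr - mse) / (msr + (k - 1) * mse)
    return icc2, icc3


TOY_TABLE = np.array(
    [[9.0, 2.0], [1.0, 10.0], [8.0, 8.0], [2.0, 6.0], [7.0, 8.0], [10.0, 6.0]]
)


def test_identical_raters_give_perfect_agreement():
    y = np.column_stack([TOY_TABLE[:, 0], TOY_TABLE[:, 0]])
    assert icc_absolute(y).icc == pytest.approx(1.0)


def test_constant_offset_breaks_absolute_agreement_only():
    """rater2 = rater1 + c: absolute-agreement ICC(2,1) < 1 while the
    consistency form ICC(3,1) stays 1 (oracle on a 6-subject toy table)."""
    y = np.column_stack([TOY_TABLE[:, 0], TOY_TABLE[:, 0] + 3.0])
    icc2_o, icc3_o = icc_oracle(y)
    res = icc_absolute(y)
    assert res.icc == pytest.approx(icc2_o, abs=1e-12)
    assert res.icc < 1.0
    assert icc3_o == pytest.approx(1.0)


def test_icc_matches_variance_components_oracle_on_toy_tables():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1))
        res = icc_absolute(y)
        assert res.icc == pytest.approx(icc_oracle(y)[0], abs=1e-12)
        assert res.ci95[0] <= res.icc <= res.ci95[1]


def test_icc_matches_pingouin_reference():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(5)
    subj = rng.normal(0, 1, 15)
    y = np.column_stack([subj + rng.normal(0, 0.4, 15),
                         subj + 0.2 + rng.normal(0, 0.4, 15)])
    ref = pg.intraclass_corr(
        pd.DataFrame({"s": np.repeat(np.arange(15), 2),
                      "r": np.tile([1, 2], 15), "y": y.ravel()}),
        targets="s", raters="r", ratings="y",
    )
    row = ref[ref.Type == "ICC(A,1)"].iloc[0]
    res = icc_absolute(y)
    assert res.icc == pytest.approx(row.ICC, abs=1e-9)
    assert res.ci95 == pytest.approx(tuple(row.CI95), abs=0.01)


def test_independent_raters_icc_near_zero():
    rng = np.random.default_rng(1)
    y = rng.normal(size=(10_000, 2))
    assert abs(icc_absolute(y).icc) < 0.03


def test_icc_symmetric_under_rater_exchange():
    res = icc_absolute(TOY_TABLE)
    swapped = icc_absolute(TOY_TABLE[:, ::-1])
    assert res.icc == pytest.approx(swapped.icc, abs=1e-12)


def test_zero_between_subject_variance_flagged_degenerate():
    y = np.column_stack([np.full(6, 2.0), np.full(6, 2.0)])
    res = icc_absolute(y)
    assert res.degenerate and res.icc == 0.0


# --------------------------------------------------------------------------
# Group comparisons

def test_exact_mann_whitney_small_sample():
    """{1,2} vs {3,4}: U = 0 and two-sided p = 1/3 (6 equally likely splits)."""
    res = compare_groups([1, 2, 0.5], [3, 4, 5])  # n=3 each keeps exact path
    assert res.test == "Mann-Whitney" or res.test == "t"
    res = compare_groups([1.0, 2.0, 1.5], [3.0, 4.0, 3.5], force_test="mwu")
    assert res.statistic == 0.0
    # direct spec example with n=2 via the internal enumerator
    from alps_glymph.stats import _mwu_exact

    u, p = _mwu_exact(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
    assert u == 0.0
    assert p == pytest.approx(1 / 3)


def test_exact_path_matches_full_enumeration_with_ties():
    from alps_glymph.stats import _mwu_exact

    rng = np.random.default_rng(7)
    for _ in range(10):
        a = rng.integers(0, 4, size=5).astype(float)
        b = rng.integers(0, 4, size=6).astype(float)
        u, p = _mwu_exact(a, b)
        # independent enumeration oracle on midranks
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n1 = len(a)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = [ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
              for idx in combinations(range(len(pooled)), n1)]
        total = comb(len(pooled), n1)
        le = sum(1 for x in us if x <= u_obs + 1e-9) / total
        ge = sum(1 for x in us if x >= u_obs - 1e-9) / total
        assert p == pytest.approx(min(1.0, 2 * min(le, ge)), abs=1e-12)


def test_exact_path_matches_scipy_without_ties():
    from alps_glymph.stats import _mwu_exact

    rng = np.random.default_rng(3)
    a = rng.normal(size=6)
    b = rng.normal(size=7) + 0.5
    _, p = _mwu_exact(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_identical_samples_p_is_one():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    res = compare_groups(x, list(x), force_test="mwu")
    assert res.p == pytest.approx(1.0)


def test_normality_gate_routes_tests():
    rng = np.random.default_rng(2)
    gauss_a = rng.normal(0, 1, 50)
    gauss_b = rng.normal(0.2, 1, 50)
    assert compare_groups(gauss_a, gauss_b).test == "t"
    skewed = np.exp(rng.normal(0, 1.5, 50))
    assert compare_groups(skewed, gauss_b).test == "Mann-Whitney"
    assert compare_groups([2.0, 2.0, 2.0, 2.0], gauss_b.tolist()).test == "Mann-Whitney"


def test_large_separation_is_highly_significant():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 40)
    b = rng.normal(3, 1, 41)   # 3 pooled SDs apart
    assert compare_groups(a, b).p < 1e-3


def test_summaries_follow_test_choice():
    rng = np.random.default_rng(6)
    res = compare_groups(rng.normal(0, 1, 30), rng.normal(0, 1, 30), force_test="t")
    assert "(" in res.summary_a            # mean (SD)
    res = compare_groups(rng.normal(0, 1, 30), rng.normal(0, 1, 30), force_test="mwu")
    assert "[" in res.summary_a            # median [range]


@settings(derandomize=True, max_examples=30)
@given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
def test_p_value_invariant_under_common_affine_transform(scale, shift):
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.8, 1, 12)
    for force in ("t", "mwu"):
        p0 = compare_groups(a, b, force_test=force).p
        p1 = compare_groups(scale * a + shift, scale * b + shift, force_test=force).p
        assert p1 == pytest.approx(p0, rel=1e-9, abs=1e-12)


def test_mwu_p_invariant_under_monotone_transform():
    rng = np.random.default_rng(10)
    a = rng.normal(1, 0.3, 15)
    b = rng.normal(1.4, 0.3, 15)
    p0 = compare_groups(a, b, force_test="mwu").p
    p1 = compare_groups(np.exp(a), np.exp(b), force_test="mwu").p
    assert p1 == pytest.approx(p0, abs=1e-12)


def test_tiny_samples_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0, 2.0], [3.0, 4.0, 5.0])


# --------------------------------------------------------------------------
# Chi-square

def test_chi_square_balanced_table_is_null():
    res = chi_square(np.array([[10, 10], [10, 10]]))
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)


def test_chi_square_hand_value():
    # expected 15 everywhere; sum (O-E)^2/E = 4 * 25/15 = 6.667
    res = chi_square(np.array([[20, 10], [10, 20]]))
    assert res.statistic == pytest.approx(6.667, abs=1e-3)


def test_chi_square_row_swap_symmetric():
    t = np.array([[20, 10], [5, 25]])
    assert chi_square(t).statistic == pytest.approx(chi_square(t[::-1]).statistic)


def test_chi_square_rejects_bad_tables():
    with pytest.raises(ValueError, match="marginal"):
        chi_square(np.array([[5, 0], [7, 0]]))
    with pytest.raises(ValueError, match="integer"):
        chi_square(np.array([[1.5, 2.0], [2.0, 1.0]]))


# --------------------------------------------------------------------------
# Spearman

def spearman_oracle(x, y):
    """Brute-force rank formula with averaged ranks for ties."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = np.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def test_spearman_monotone_extremes():
    x = [1.0, 2.0, 5.0, 9.0, 11.0]
    assert spearman(x, [2.0, 3.0, 8.0, 9.0, 20.0])[0] == pytest.approx(1.0)
    assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)


def test_spearman_tied_data_matches_rank_oracle():
    x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0]
    y = [4.0, 4.0, 6.0, 2.0, 9.0, 9.0, 1.0, 7.0]
    r, p = spearman(x, y)
    assert r == pytest.approx(spearman_oracle(x, y), abs=1e-12)
    # p from the t-approximation on n-2 df
    t = r * np.sqrt((len(x) - 2) / (1 - r**2))
    assert p == pytest.approx(2 * sps.t.sf(abs(t), len(x) - 2), abs=1e-9)


def test_spearman_constant_input_flagged():
    with pytest.raises(ValueError, match="constant"):
        spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# --------------------------------------------------------------------------
# Regression

def test_noiseless_linear_data_recovered_exactly():
    x = np.arange(10, dtype=float)
    res = ols_adjusted(2.0 * x, {"x": x})
    e = res.effect("x")
    assert e.beta == pytest.approx(2.0, abs=1e-9)
    assert e.ci95[1] - e.ci95[0] == pytest.approx(0.0, abs=1e-7)


def test_multipredictor_noiseless_recovery():
    rng = np.random.default_rng(0)
    X = {k: rng.normal(size=30) for k in ("a", "b", "c")}
    y = 1.5 + 2.0 * X["a"] - 0.7 * X["b"] + 0.01 * X["c"]
    res = ols_adjusted(y, X)
    assert res.effect("a").beta == pytest.approx(2.0, abs=1e-9)
    assert res.effect("b").beta == pytest.approx(-0.7, abs=1e-9)
    assert res.effect("c").beta == pytest.approx(0.01, abs=1e-9)


def test_ci_coverage_for_adjusted_effect():
    """y = -7*alps + noise at n=41: the 95% CI covers -7 in >=90% of 200 reps."""
    rng = np.random.default_rng(12)
    hits = 0
    betas = []
    for _ in range(200):
        alps = rng.normal(1.074, 0.225, 41)
        age = rng.normal(68, 6, 41)          # irrelevant covariate
        y = -7.0 * alps + rng.normal(0, 1.0, 41)
        res = ols_adjusted(y, {"alps": alps, "age": age})
        e = res.effect("alps")
        hits += e.ci95[0] <= -7.0 <= e.ci95[1]
        betas.append(e.beta)
    assert hits >= 180
    assert np.mean(betas) == pytest.approx(-7.0, rel=0.05)  # unbiased w/ nuisance


def test_rank_deficiency_names_collinear_columns():
    x = np.arange(12, dtype=float)
    with pytest.raises(ValueError, match="x2"):
        ols_adjusted(x, {"x1": x, "x2": 2 * x})


def test_underdetermined_design_rejected():
    with pytest.raises(ValueError, match="n >"):
        ols_adjusted([1.0, 2.0, 3.0], {"a": [1, 2, 3], "b": [4, 5, 7]})


# --------------------------------------------------------------------------
# ROC

def auc_oracle(scores, disease):
    """All-pairs concordance fraction: lower score should flag disease."""
    pos = [s for s, d in zip(scores, disease) if d]
    neg = [s for s, d in zip(scores, disease) if not d]
    acc = 0.0
    for p in pos:
        for n in neg:
            acc += 1.0 if p < n else (0.5 if p == n else 0.0)
    return acc / (len(pos) * len(neg))


def test_perfect_separation():
    res = roc_analysis([1.0, 1.1, 1.2, 1.6, 1.7, 1.8],
                       [True, True, True, False, False, False])
    assert res.auc == 1.0
    assert res.sensitivity_pct == 100.0
    assert res.specificity_pct == 100.0
    assert 1.2 <= res.cutoff < 1.6


def test_identical_distributions_auc_half():
    rng = np.random.default_rng(8)
    s = rng.normal(size=400)
    labels = np.arange(400) < 200
    assert abs(roc_analysis(s, labels).auc - 0.5) < 0.08


def test_six_point_toy_matches_all_pairs_oracle():
    scores = [1.0, 1.2, 1.2, 1.5, 1.1, 1.9]
    disease = [True, True, False, False, True, False]
    assert roc_analysis(scores, disease).auc == pytest.approx(
        auc_oracle(scores, disease)
    )


def test_auc_equals_concordance_oracle_on_random_inputs():
    rng = np.random.default_rng(13)
    for _ in range(50):
        n = int(rng.integers(4, 15))
        scores = np.round(rng.normal(size=n), 1)       # rounding forces ties
        disease = rng.random(n) < 0.5
        if disease.all() or not disease.any():
            continue
        res = roc_analysis(scores, disease)
        assert res.auc == pytest.approx(auc_oracle(scores, disease), abs=1e-12)


def test_auc_matches_sklearn_reference():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(14)
    scores = rng.normal(size=60)
    disease = rng.random(60) < 0.4
    res = roc_analysis(scores, disease)
    # sklearn scores "higher = positive": negate for the disease orientation
    assert res.auc == pytest.approx(roc_auc_score(disease, -scores), abs=1e-12)


def test_youden_cutoff_tie_break_prefers_sensitivity():
    # two cutoffs share J; the one classifying more patients positive wins
    scores = [1.0, 1.2, 2.0, 2.2]
    disease = [True, True, False, False]
    res = roc_analysis(scores, disease)
    assert res.sensitivity_pct == 100.0


def test_single_class_rejected():
    with pytest.raises(ValueError, match="classes"):
        roc_analysis([1.0, 2.0], [True, True])
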