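import numpy as np
import pandas as pd
import pytest

from ienfa.stats import (
    StatsError,
    compare_groups,
    cv,
    delong_test,
    holm_adjust,
    icc,
    icc_bootstrap_compare,
    linreg,
    pearson,
    roc,
    standardized_coefficient,
    steiger_z,
)


# ---------------------------------------------------------------------------
# ICC


def _icc_anova_oracle(table, kind):
    """Naive loop-based two-way ANOVA, independent of the implementation."""
    n, k = len(table), len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (table[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    if kind == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


TOY_TABLE = np.array([[7.0, 9.0], [5.0, 6.0], [8.0, 7.0], [2.0, 4.0]])


@pytest.mark.parametrize("kind", ["agreement", "consistency"])
def test_icc_matches_anova_oracle(kind):
    got = icc(TOY_TABLE, kind).estimate
    assert got == pytest.approx(_icc_anova_oracle(TOY_TABLE.tolist(), kind))


@pytest.mark.parametrize("kind", ["agreement", "consistency"])
def test_icc_identical_columns_is_one(kind):
    table = np.tile(np.array([[3.0], [5.0], [9.0], [1.0]]), (1, 3))
    assert icc(table, kind).estimate == pytest.approx(1.0)


def test_icc_systematic_offset():
    base = np.array([3.0, 5.0, 9.0, 1.0, 6.0])
    table = np.column_stack([base, base + 5.0])
    assert icc(table, "consistency").estimate == pytest.approx(1.0)
    agreement = icc(table, "agreement").estimate
    assert agreement < 1.0
    assert agreement == pytest.approx(_icc_anova_oracle(table.tolist(), "agreement"))


def test_icc_against_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    table = rng.normal(5, 2, size=(12, 3)) + rng.normal(0, 1, size=(12, 1))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": table.ravel(),
        }
    )
    res = pingouin.intraclass_corr(
        long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    assert icc(table, "agreement").estimate == pytest.approx(
        res.loc["ICC(A,1)", "ICC"], abs=1e-9
    )
    assert icc(table, "consistency").estimate == pytest.approx(
        res.loc["ICC(C,1)", "ICC"], abs=1e-9
    )


def test_icc_degenerate_inputs_rejected():
    with pytest.raises(StatsError):
        icc(np.full((4, 2), 3.0))  # zero subject variance
    with pytest.raises(StatsError):
        icc(np.array([[1.0, np.nan], [2.0, 3.0]]))
    with pytest.raises(StatsError):
        icc(np.array([[1.0], [2.0]]))  # single rater


# ---------------------------------------------------------------------------
# Bootstrap ICC comparison


def test_bootstrap_identical_biomarkers_never_significant():
    rng = np.random.default_rng(1)
    truth = rng.normal(1.0, 0.5, 40)
    table = np.column_stack([truth + rng.normal(0, 0.1, 40) for _ in range(2)])
    comp = icc_bootstrap_compare({"a": table, "b": table.copy()}, n_boot=300, seed=0)
    row = comp.pairs.iloc[0]
    assert row.ci_low <= 0 <= row.ci_high
    assert not row.significant_ci and not row.significant_holm


def test_bootstrap_detects_reliability_ordering():
    """With n = 60 subjects, a low-noise biomarker's ICC beats a high-noise
    one's in at least 90% of replicate studies (CI excludes zero)."""
    detected = 0
    n_rep = 50
    for rep in range(n_rep):
        rng = np.random.default_rng(100 + rep)
        truth = rng.normal(1.0, 0.5, 60)
        good = np.column_stack([truth + rng.normal(0, 0.05, 60) for _ in range(2)])
        bad = np.column_stack([truth + rng.normal(0, 0.5, 60) for _ in range(2)])
        comp = icc_bootstrap_compare({"good": good, "bad": bad}, n_boot=300, seed=rep)
        row = comp.pairs.iloc[0]
        if row.ci_low > 0:
            detected += 1
    assert detected >= 0.9 * n_rep


def test_bootstrap_deterministic_under_seed():
    rng = np.random.default_rng(2)
    truth = rng.normal(1.0, 0.5, 30)
    tables = {
        "a": np.column_stack([truth + rng.normal(0, 0.1, 30) for _ in range(2)]),
        "b": np.column_stack([truth + rng.normal(0, 0.2, 30) for _ in range(2)]),
    }
    c1 = icc_bootstrap_compare(tables, n_boot=200, seed=7)
    c2 = icc_bootstrap_compare(tables, n_boot=200, seed=7)
    pd.testing.assert_frame_equal(c1.pairs, c2.pairs)


def test_bootstrap_small_b_warns():
    rng = np.random.default_rng(3)
    truth = rng.normal(1, 0.5, 20)
    tables = {
        "a": np.column_stack([truth, truth + rng.normal(0, 0.1, 20)]),
        "b": np.column_stack([truth, truth + rng.normal(0, 0.1, 20)]),
    }
    with pytest.warns(UserWarning, match="small"):
        icc_bootstrap_compare(tables, n_boot=50, seed=0)


# ---------------------------------------------------------------------------
# Holm


def test_holm_hand_worked_example():
    np.testing.assert_allclose(
        holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
    )


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_holm_adjustment_properties(ps):
        """Adjusted p-values dominate the raw ones, respect their ordering
        and stay in [0, 1]."""
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_holm_edge_cases():
    assert holm_adjust([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(StatsError):
        holm_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Regression and correlation


def test_linreg_exact_line():
    x = pd.DataFrame({"x": np.arange(10.0)})
    y = 2.0 * x["x"].to_numpy() + 1.0
    fit = linreg(y, x)
    assert fit.params.loc["x", "coef"] == pytest.approx(2.0)
    assert fit.params.loc["const", "coef"] == pytest.approx(1.0)
    assert fit.params.loc["x", "ci_high"] - fit.params.loc["x", "ci_low"] == pytest.approx(0.0, abs=1e-8)


def test_linreg_row_permutation_invariance():
    rng = np.random.default_rng(0)
    x = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
    y = 1.5 * x["a"].to_numpy() - 0.5 * x["b"].to_numpy() + rng.normal(size=30)
    perm = rng.permutation(30)
    f1 = linreg(y, x)
    f2 = linreg(y[perm], x.iloc[perm].reset_index(drop=True))
    pd.testing.assert_frame_equal(f1.params, f2.params)


def test_linreg_rank_deficiency_rejected():
    x = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
    with pytest.raises(StatsError):
        linreg(np.arange(10.0), x)


def test_standardized_coefficient_identity():
    """beta_std = beta x SD(x)/SD(y): the printed raw age slope of IENFd
    (-0.105/yr) with SDs 13.0 and 2.94 standardizes to about -0.46."""
    got = standardized_coefficient(-0.105, 13.0, 2.94)
    assert got == pytest.approx(-0.4643, abs=1e-4)
    assert abs(got - (-0.46)) <= 0.005


def test_linreg_standardized_matches_identity():
    rng = np.random.default_rng(4)
    x = pd.DataFrame({"x": rng.normal(50, 13, 200)})
    y = -0.1 * x["x"].to_numpy() + rng.normal(0, 2, 200)
    fit = linreg(y, x, standardize=True)
    expect = standardized_coefficient(
        fit.params.loc["x", "coef"], x["x"].std(ddof=1), np.std(y, ddof=1)
    )
    assert fit.standardized.loc["x", "coef"] == pytest.approx(expect)


def test_pearson_examples_and_oracle():
    x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
    y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
    r, (lo, hi), p = pearson(x, y)
    # explicit product-moment arithmetic
    xc, yc = x - x.mean(), y - y.mean()
    expect = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    assert r == pytest.approx(expect)
    assert lo < r < hi
    r1, _, _ = pearson(x, x)
    assert r1 == pytest.approx(1.0)


def test_pearson_null_is_small():
    rng = np.random.default_rng(6)
    r, _, _ = pearson(rng.normal(size=10_000), rng.normal(size=10_000))
    assert abs(r) < 0.05


def test_pearson_zero_variance_rejected():
    with pytest.raises(StatsError):
        pearson(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# Steiger's Z


def _steiger_oracle(r_xy, r_xz, r_yz, n):
    """Literal transcription of the dependent-correlation Z formula."""
    import math

    rbar = (r_xy + r_xz) / 2.0
    psi = r_yz * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_yz**2)
    c = psi / ((1 - rbar**2) ** 2)
    z1 = 0.5 * math.log((1 + r_xy) / (1 - r_xy))
    z2 = 0.5 * math.log((1 + r_xz) / (1 - r_xz))
    return (z1 - z2) * math.sqrt((n - 3) / (2 - 2 * c))


def test_steiger_formula_oracle():
    z, p = steiger_z(0.5, 0.3, 0.6, 100)
    assert z == pytest.approx(_steiger_oracle(0.5, 0.3, 0.6, 100))
    assert 0 < p < 0.05


def test_steiger_symmetry_and_antisymmetry():
    z, p = steiger_z(0.4, 0.4, 0.2, 50)
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    z1, _ = steiger_z(0.5, 0.2, 0.3, 80)
    z2, _ = steiger_z(0.2, 0.5, 0.3, 80)
    assert z1 == pytest.approx(-z2)


def test_steiger_inconsistent_matrix_rejected():
    with pytest.raises(StatsError):
        steiger_z(0.9, 0.9, -0.9, 50)
    with pytest.raises(StatsError):
        steiger_z(1.0, 0.5, 0.5, 50)


def test_steiger_null_p_uniform():
    """Under a null with equal population correlations the p-values are
    approximately uniform (seeded simulation)."""
    rng = np.random.default_rng(12)
    n, reps = 60, 400
    cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.4], [0.5, 0.4, 1.0]])
    chol = np.linalg.cholesky(cov)
    ps = []
    for _ in range(reps):
        data = rng.standard_normal((n, 3)) @ chol.T
        r = np.corrcoef(data.T)
        try:
            _, p = steiger_z(r[0, 1], r[0, 2], r[1, 2], n)
            ps.append(p)
        except StatsError:
            continue
    ps = np.asarray(ps)
    assert abs(np.mean(ps < 0.05) - 0.05) < 0.03
    assert abs(ps.mean() - 0.5) < 0.05


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    scores = np.array([0.1, 0.2, 0.3, 2.0, 2.5, 3.0])
    labels = np.array([1, 1, 1, 0, 0, 0], bool)  # disease at low values
    res = roc(scores, labels)
    assert res.auc == 1.0
    assert res.youden_j == 1.0
    assert res.orientation == "low_is_disease"
    assert 0.3 < res.threshold < 2.0


def test_roc_null_auc_near_half():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=2000)
    labels = rng.uniform(size=2000) < 0.5
    res = roc(scores, labels)
    assert res.auc == pytest.approx(0.5, abs=0.03)


def test_roc_tie_handling_matches_pair_counting():
    scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
    labels = np.array([1, 1, 0, 0, 1, 0], bool)
    res = roc(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]
    conc = sum((p < q) + 0.5 * (p == q) for p in pos for q in neg)
    expected = conc / (len(pos) * len(neg))
    assert res.auc == pytest.approx(max(expected, 1 - expected))


def test_roc_equals_mann_whitney_and_sklearn_on_random_inputs():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(8)
    for _ in range(20):
        n = rng.integers(10, 60)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.uniform(size=n) < 0.5
        if labels.all() or not labels.any():
            continue
        res = roc(scores, labels)
        sk = roc_auc_score(labels, scores)
        assert res.auc == pytest.approx(max(sk, 1 - sk))


def test_roc_youden_threshold_separates_best():
    scores = np.array([0.1, 0.4, 0.5, 0.9, 1.2, 1.5, 2.0, 2.2])
    labels = np.array([1, 1, 1, 0, 1, 0, 0, 0], bool)
    res = roc(scores, labels)
    # recompute J at the reported threshold with the reported orientation
    called = scores <= res.threshold
    sens = (called & labels).sum() / labels.sum()
    spec = (~called & ~labels).sum() / (~labels).sum()
    assert sens + spec - 1 == pytest.approx(res.youden_j)
    # exhaustive check that no cut-point does better
    best = max(
        ((scores <= t) & labels).sum() / labels.sum()
        + (~(scores <= t) & ~labels).sum() / (~labels).sum()
        - 1
        for t in np.concatenate([scores, [scores.min() - 1, scores.max() + 1]])
    )
    assert res.youden_j == pytest.approx(best)


def test_roc_single_class_rejected():
    with pytest.raises(StatsError):
        roc(np.arange(5.0), np.ones(5, bool))


# ---------------------------------------------------------------------------
# DeLong


def test_delong_identical_scores():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=50)
    labels = rng.uniform(size=50) < 0.4
    auc_a, auc_b, z, p = delong_test(scores, scores.copy(), labels)
    assert auc_a == auc_b
    assert z == 0.0 and p == 1.0


def test_delong_aucs_match_roc():
    rng = np.random.default_rng(5)
    labels = rng.uniform(size=80) < 0.5
    a = labels + rng.normal(0, 0.7, 80)
    b = labels + rng.normal(0, 1.5, 80)
    auc_a, auc_b, _, _ = delong_test(a, b, labels)
    assert auc_a == pytest.approx(roc(a, labels).auc)
    assert auc_b == pytest.approx(roc(b, labels).auc)


def test_delong_rank_agrees_with_bootstrap_oracle():
    """On a small paired set, DeLong's significance call at 0.05 agrees
    with a subject-level bootstrap of the AUC difference."""
    rng = np.random.default_rng(10)
    n = 60
    labels = rng.uniform(size=n) < 0.5
    good = labels * 2.0 + rng.normal(0, 0.5, n)
    noise = rng.normal(size=n)
    for b_scores, expect_sig in ((good + rng.normal(0, 0.1, n), False), (noise, True)):
        auc_a, auc_b, z, p = delong_test(good, b_scores, labels)
        diffs = []
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            if labels[idx].all() or not labels[idx].any():
                continue
            da = roc(good[idx], labels[idx]).auc
            db = roc(b_scores[idx], labels[idx]).auc
            diffs.append(da - db)
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        boot_sig = not (lo <= 0 <= hi)
        assert (p < 0.05) == boot_sig == expect_sig


# ---------------------------------------------------------------------------
# Group comparisons and CV


def test_compare_groups_fisher_extreme_table():
    """A perfectly separated 2x2 table (hand hypergeometric: p = 2/C(20,10)
    ~ 1.1e-5) goes through Fisher's exact test."""
    df = pd.DataFrame(
        {"group": ["a"] * 10 + ["b"] * 10, "sex": ["M"] * 10 + ["F"] * 10}
    )
    res = compare_groups(df, "sex")
    assert res.kind == "fisher"
    assert res.p < 0.001
    from math import comb

    assert res.p == pytest.approx(2 / comb(20, 10))


def test_compare_groups_chi2_for_large_balanced():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "group": np.repeat(["a", "b"], 200),
            "sex": rng.choice(["M", "F"], 400),
        }
    )
    assert compare_groups(df, "sex").kind == "chi2"


def test_compare_groups_age_confounding_removed():
    """A group difference produced purely by an age imbalance vanishes
    after adjustment for age."""
    rng = np.random.default_rng(3)
    n = 300
    age_a = rng.normal(65, 5, n)
    age_b = rng.normal(45, 5, n)
    df = pd.DataFrame(
        {
            "group": np.repeat(["a", "b"], n),
            "age": np.concatenate([age_a, age_b]),
            "sex": rng.choice(["M", "F"], 2 * n),
        }
    )
    df["y"] = -0.1 * df["age"] + rng.normal(0, 0.5, 2 * n)
    res = compare_groups(df, "y", adjust_for=("age", "sex"))
    assert res.p < 1e-6  # unadjusted: groups differ strongly
    assert res.adjusted_p > 0.05


def test_compare_groups_type_one_error_rate():
    """Under the null the gated test rejects at ~5% (1,000 replicates)."""
    rng = np.random.default_rng(7)
    rejections = 0
    reps = 1000
    for i in range(reps):
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 20),
                "y": rng.normal(size=40),
            }
        )
        if compare_groups(df, "y").p < 0.05:
            rejections += 1
    assert abs(rejections / reps - 0.05) <= 0.02


def test_compare_groups_validation():
    df = pd.DataFrame({"group": ["a"] * 3, "y": [1.0, 2.0, 3.0]})
    with pytest.raises(StatsError):
        compare_groups(df, "y")


def test_cv_examples():
    assert cv(np.full(5, 3.0)) == 0.0
    assert cv(np.array([8.0, 12.0])) == pytest.approx(28.2843, abs=1e-3)
    vals = np.array([2.0, 3.0, 5.0, 9.0])
    assert cv(vals * 7.0) == pytest.approx(cv(vals))
    with pytest.raises(StatsError):
        cv(np.array([-1.0, 1.0]))
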