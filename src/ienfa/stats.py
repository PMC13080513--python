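"""Validation statistics for biomarker studies.

Reliability (two-way single-measure ICC with a subject-level cluster
bootstrap, percentile CIs and Holm correction for the family of pairwise
biomarker comparisons), association (Pearson with Fisher-z CI, ordinary
least squares with standardized coefficients, Steiger's Z for dependent
correlations sharing a variable), diagnosis (empirical ROC with the
Youden-maximal threshold and DeLong's test for paired AUCs) and descriptive
group comparisons with a Shapiro–Wilk normality gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError",
    "IccResult",
    "IccComparison",
    "RegressionResult",
    "RocResult",
    "GroupComparison",
    "icc",
    "icc_bootstrap_compare",
    "holm_adjust",
    "linreg",
    "standardized_coefficient",
    "pearson",
    "steiger_z",
    "roc",
    "delong_test",
    "compare_groups",
    "cv",
]


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reliability


@dataclass(frozen=True)
class IccResult:
    """Single-measure intraclass correlation from a two-way design."""

    icc_type: str  # "agreement" | "consistency"
    estimate: float
    n_subjects: int
    n_raters: int


def icc(ratings: np.ndarray, icc_type: str = "agreement") -> IccResult:
    """Two-way ANOVA single-measure ICC of a complete n x k ratings table.

    ``agreement`` (default) penalises systematic rater offsets (absolute
    agreement, random raters); ``consistency`` does not.
    """
    if icc_type not in {"agreement", "consistency"}:
        raise StatsError(f"unknown ICC type {icc_type!r}")
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise StatsError("ratings must be an n>=2 by k>=2 table")
    if np.isnan(r).any():
        raise StatsError("ratings table has missing cells")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((r - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_rows == 0 and ss_err == 0:
        raise StatsError("zero variance across subjects: ICC undefined")
    if icc_type == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise StatsError("degenerate ratings table: ICC undefined")
    return IccResult(
        icc_type=icc_type,
        estimate=float((msr - mse) / denom),
        n_subjects=n,
        n_raters=k,
    )


@dataclass(frozen=True)
class IccComparison:
    """Bootstrap comparison of biomarker ICCs at the subject level."""

    biomarkers: tuple[str, ...]
    point_estimates: dict[str, float]
    boot_icc: dict[str, np.ndarray] = field(repr=False)
    pairs: pd.DataFrame  # a, b, diff, ci_low, ci_high, p_boot, p_holm, ...
    icc_type: str
    n_boot: int
    seed: int
    n_redrawn: int


def icc_bootstrap_compare(
    ratings: dict[str, np.ndarray],
    icc_type: str = "agreement",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> IccComparison:
    """Compare biomarker ICCs via a subject-level non-parametric bootstrap.

    Subjects (rows, shared across biomarkers) are resampled with replacement
    ``n_boot`` times; every biomarker's ICC is recomputed per replicate.
    Pairwise ICC differences get percentile CIs, bootstrap p-values
    (two-sided tail proportion, floored at 1/B) and Holm-adjusted p-values.
    ``significant_ci`` follows the CI-excludes-zero rule; ``significant_holm``
    the adjusted-p rule.  Degenerate resamples with zero subject variance
    are redrawn (count reported).
    """
    if len(ratings) < 2:
        raise StatsError("need at least two biomarkers to compare")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for percentile CIs", stacklevel=2)
    names = tuple(ratings)
    tables = {m: np.asarray(ratings[m], dtype=float) for m in names}
    n = tables[names[0]].shape[0]
    for m, t in tables.items():
        if t.shape[0] != n:
            raise StatsError("biomarker tables must share subjects")
    point = {m: icc(t, icc_type).estimate for m, t in tables.items()}

    rng = np.random.default_rng(seed)
    boot = {m: np.empty(n_boot) for m in names}
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            try:
                vals = {m: icc(tables[m][idx], icc_type).estimate for m in names}
                break
            except StatsError:
                n_redrawn += 1
        else:  # pragma: no cover - pathological input
            raise StatsError("could not draw a non-degenerate bootstrap sample")
        for m in names:
            boot[m][b] = vals[m]

    rows = []
    for i, a in enumerate(names):
        for b2 in names[i + 1 :]:
            d = boot[a] - boot[b2]
            lo, hi = np.percentile(d, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            p = max(2 * min(np.mean(d <= 0), np.mean(d >= 0)), 1.0 / n_boot)
            rows.append(
                {
                    "a": a,
                    "b": b2,
                    "diff": point[a] - point[b2],
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_boot": min(p, 1.0),
                }
            )
    pairs = pd.DataFrame(rows)
    pairs["p_holm"] = holm_adjust(pairs["p_boot"].to_numpy())
    pairs["significant_ci"] = (pairs["ci_low"] > 0) | (pairs["ci_high"] < 0)
    pairs["significant_holm"] = pairs["p_holm"] < alpha
    return IccComparison(
        biomarkers=names,
        point_estimates=point,
        boot_icc=boot,
        pairs=pairs,
        icc_type=icc_type,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Association


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit: coefficient table and optional standardized coefficients."""

    params: pd.DataFrame  # index: term; columns: coef, ci_low, ci_high, p
    standardized: pd.DataFrame | None
    n: int
    r_squared: float


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def linreg(
    y: np.ndarray | pd.Series,
    x: pd.DataFrame,
    standardize: bool = False,
) -> RegressionResult:
    """Ordinary least squares of ``y`` on the covariates in ``x``.

    With ``standardize=True`` a parallel fit is run with every continuous
    variable (more than two distinct values) and the response z-scored; its
    slopes are the standardized coefficients.
    """
    y = np.asarray(y, dtype=float)
    x = pd.DataFrame(x).astype(float)
    n = len(y)
    if n <= x.shape[1] + 1:
        raise StatsError("need more observations than parameters")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise StatsError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int()
    params = pd.DataFrame(
        {
            "coef": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
    standardized = None
    if standardize:
        xs = x.copy()
        for c in xs.columns:
            if xs[c].nunique() > 2:
                xs[c] = _zscore(xs[c].to_numpy())
        fit_s = sm.OLS(_zscore(y), sm.add_constant(xs)).fit()
        ci_s = fit_s.conf_int()
        standardized = pd.DataFrame(
            {
                "coef": fit_s.params,
                "ci_low": ci_s[0],
                "ci_high": ci_s[1],
                "p": fit_s.pvalues,
            }
        )
    return RegressionResult(
        params=params, standardized=standardized, n=n, r_squared=fit.rsquared
    )


def standardized_coefficient(beta: float, sd_x: float, sd_y: float) -> float:
    """Standardized slope: beta x SD(x)/SD(y) (single-term standardization)."""
    if sd_x <= 0 or sd_y <= 0:
        raise StatsError("standard deviations must be positive")
    return beta * sd_x / sd_y


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """Pearson r with Fisher-z 95% CI and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    n = len(x)
    if n > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959963985 * se), np.tanh(z + 1.959963985 * se)
    else:
        lo, hi = -1.0, 1.0
    return float(r), (float(lo), float(hi)), float(p)


def steiger_z(r_xy: float, r_xz: float, r_yz: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable x.

    Tests H0: rho(x,y) = rho(x,z) given the correlation r(y,z) between the
    two non-shared variables, via Fisher transforms and the shared-variable
    covariance term (pooled-r variant).  Returns (Z, two-sided p).
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 < r < 1.0:
            raise StatsError("correlations must lie strictly in (-1, 1)")
    if n <= 3:
        raise StatsError("need n > 3")
    corr = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1.0]])
    if np.linalg.det(corr) <= 0:
        raise StatsError("inconsistent correlation inputs (non-PSD matrix)")
    rbar = 0.5 * (r_xy + r_xz)
    psi = r_yz * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_yz**2)
    cbar = psi / (1 - rbar**2) ** 2
    z1, z2 = np.arctanh(r_xy), np.arctanh(r_xz)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * cbar))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Diagnosis


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary with the Youden-optimal cut-point."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    stratum: str
    orientation: str  # "low_is_disease" | "high_is_disease"
    n_pos: int
    n_neg: int


def roc(
    scores: np.ndarray,
    labels: np.ndarray,
    stratum: str = "all",
) -> RocResult:
    """Empirical ROC over all observed cut-points with trapezoidal AUC.

    ``labels`` are boolean disease indicators.  The biomarker is oriented so
    that the AUC is at least 0.5 (disease is expected at low biomarker
    values; the realised orientation is reported).  Candidate thresholds are
    midpoints between consecutive distinct scores plus infinite sentinels;
    Youden ties resolve to the threshold with higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise StatsError("scores and labels must be paired")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatsError(f"stratum {stratum!r} lacks one of the classes")

    def _auc_for(sc: np.ndarray) -> float:
        # Mann-Whitney with ties counted half: P(score_pos < score_neg) for
        # the low-is-disease orientation after negation.
        pos = sc[labels]
        neg = sc[~labels]
        greater = np.sum(pos[:, None] > neg[None, :])
        ties = np.sum(pos[:, None] == neg[None, :])
        return (greater + 0.5 * ties) / (n_pos * n_neg)

    auc_low = _auc_for(-scores)
    if auc_low >= 0.5:
        orientation = "low_is_disease"
        oriented = -scores
        auc = auc_low
    else:
        orientation = "high_is_disease"
        oriented = scores
        auc = 1.0 - auc_low

    uniq = np.unique(oriented)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cand = np.concatenate(([-np.inf], mids, [np.inf]))
    best = None
    for t in cand:
        called = oriented >= t
        sens = np.sum(called & labels) / n_pos
        spec = np.sum(~called & ~labels) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, t)
    j, sens, spec, t = best
    threshold = -t if orientation == "low_is_disease" else t
    return RocResult(
        auc=float(auc),
        threshold=float(threshold),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j),
        stratum=stratum,
        orientation=orientation,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _delong_placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and structural components (placement values) of one marker."""
    v_pos = np.array(
        [np.mean((p > neg) + 0.5 * (p == neg)) for p in pos]
    )
    v_neg = np.array(
        [np.mean((pos > q) + 0.5 * (pos == q)) for q in neg]
    )
    return float(v_pos.mean()), v_pos, v_neg


def delong_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs on the same subjects.

    Returns ``(auc_a, auc_b, z, p)``; scores are oriented so high values
    indicate disease (callers comparing low-is-disease biomarkers should
    negate consistently — the test statistic is invariant to joint
    negation up to AUC reflection).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise StatsError("scores must be paired on identical subjects")
    pos, neg = labels, ~labels
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise StatsError("both classes must be present")
    auc_a, va_pos, va_neg = _delong_placements(scores_a[pos], scores_a[neg])
    auc_b, vb_pos, vb_neg = _delong_placements(scores_b[pos], scores_b[neg])
    s_pos = np.cov(np.vstack([va_pos, vb_pos]))
    s_neg = np.cov(np.vstack([va_neg, vb_neg]))
    var = (
        (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m
        + (s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) > 1e-12:
            raise StatsError("zero estimated variance with unequal AUCs")
        return auc_a, auc_b, 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


# ---------------------------------------------------------------------------
# Descriptive comparisons


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: str  # "t-test" | "rank-sum" | "chi2" | "fisher"
    statistic: float
    p: float
    adjusted_p: float | None
    group_means: dict[str, float] | None


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    adjust_for: tuple[str, ...] = (),
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Two-group comparison with a Shapiro–Wilk normality gate.

    Continuous variables: t-test when both groups pass Shapiro–Wilk at
    ``alpha_normality``, Wilcoxon rank-sum otherwise.  Categorical
    variables: chi-squared, falling back to Fisher's exact test when any
    expected cell is 5 or less (2x2 tables).  With ``adjust_for``, the
    adjusted p-value is the group-term p from an OLS model with the listed
    covariates (sex coded numerically when present).
    """
    groups = cohort[group_col].dropna().unique()
    if len(groups) != 2:
        raise StatsError(f"need exactly two groups, got {list(groups)}")
    ga = cohort[cohort[group_col] == groups[0]]
    gb = cohort[cohort[group_col] == groups[1]]
    if ga.empty or gb.empty:
        raise StatsError("both groups must be non-empty")

    col = cohort[variable]
    if pd.api.types.is_numeric_dtype(col):
        a = ga[variable].dropna().to_numpy(dtype=float)
        b = gb[variable].dropna().to_numpy(dtype=float)
        normal = (
            sps.shapiro(a).pvalue > alpha_normality
            and sps.shapiro(b).pvalue > alpha_normality
        )
        if normal:
            stat, p = sps.ttest_ind(a, b)
            kind = "t-test"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            kind = "rank-sum"
        adj = None
        if adjust_for:
            df = cohort[[variable, group_col, *adjust_for]].dropna().copy()
            x = pd.DataFrame(index=df.index)
            x["group"] = (df[group_col] == groups[0]).astype(float)
            for c in adjust_for:
                if pd.api.types.is_numeric_dtype(df[c]):
                    x[c] = df[c].astype(float)
                else:
                    x[c] = pd.factorize(df[c])[0].astype(float)
            fit = linreg(df[variable].to_numpy(), x)
            adj = float(fit.params.loc["group", "p"])
        return GroupComparison(
            variable=variable,
            kind=kind,
            statistic=float(stat),
            p=float(p),
            adjusted_p=adj,
            group_means={str(groups[0]): float(a.mean()), str(groups[1]): float(b.mean())},
        )

    table = pd.crosstab(cohort[group_col], col).to_numpy()
    chi2, p, _, expected = sps.chi2_contingency(table)
    if (expected <= 5).any() and table.shape == (2, 2):
        stat, p = sps.fisher_exact(table)
        kind = "fisher"
    else:
        stat, kind = chi2, "chi2"
    return GroupComparison(
        variable=variable,
        kind=kind,
        statistic=float(stat),
        p=float(p),
        adjusted_p=None,
        group_means=None,
    )


def cv(values: np.ndarray) -> float:
    """Coefficient of variation: 100 x sample SD / mean, in percent."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        raise StatsError("coefficient of variation undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)
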