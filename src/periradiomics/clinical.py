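"""Univariate clinical statistics: contingency tests, group comparisons,
odds ratios, and logistic regression.

The 2x2 chi-square statistics are computed in closed form (Pearson and
Yates continuity-corrected); the dispatch rule used for baseline tables
is the conventional one that reproduces this cohort's published layer
exactly: Pearson when all expected counts are >= 5, continuity-corrected
chi-square when any expected count is below 5, Fisher's exact test when
any expected count is below 1.

Continuous variables pass through a Shapiro-Wilk normality gate per
group (alpha 0.05): pooled-variance t-test when both groups look normal,
Mann-Whitney U otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "OrResult",
    "pearson_chi2",
    "fisher_exact",
    "chi2_dispatch",
    "odds_ratio_wald",
    "mann_whitney_u",
    "group_compare",
    "logistic_regression",
    "table_one",
]

_Z95 = 1.96  # Wald CIs use z = 1.96 exactly


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class OrResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool = False  # Haldane 0.5 continuity correction applied


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of non-negative integer counts")
    return t


def pearson_chi2(table, correction: str = "none") -> TestResult:
    """2x2 chi-square: ``none`` -> n(ad-bc)^2/(r1 r2 c1 c2); ``yates`` ->
    n(max(|ad-bc|-n/2, 0))^2 / (r1 r2 c1 c2).  df = 1."""
    t = _as_2x2(table)
    a, b, c, d = t.ravel()
    n = t.sum()
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    if 0 in (r1, r2, c1, c2):
        raise ValueError("zero marginal total")
    if correction == "none":
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    elif correction == "yates":
        stat = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2 / (r1 * r2 * c1 * c2)
    else:
        raise ValueError("correction must be 'none' or 'yates'")
    return TestResult(statistic=float(stat), df=1,
                      p=float(stats.chi2.sf(stat, 1)),
                      method="pearson" if correction == "none" else "yates")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test (sum of hypergeometric probabilities
    no larger than the observed table's)."""
    t = _as_2x2(table)
    if 0 in np.concatenate([t.sum(axis=0), t.sum(axis=1)]):
        return TestResult(statistic=np.nan, df=None, p=1.0, method="fisher")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=np.nan, df=None, p=float(p), method="fisher")


def chi2_dispatch(table) -> TestResult:
    """Baseline-table dispatch: Pearson / Yates / Fisher by expected counts."""
    t = _as_2x2(table)
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (exp < 1).any():
        return fisher_exact(t)
    if (exp < 5).any():
        return pearson_chi2(t, correction="yates")
    return pearson_chi2(t, correction="none")


def rxc_chi2(table) -> TestResult:
    """Generic r x c Pearson chi-square, sum (O-E)^2 / E.

    Empty rows/columns are dropped; a table degenerate after dropping
    (fewer than 2 levels on either margin) carries no association and
    returns statistic 0, p = 1.
    """
    t = np.asarray(table, float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return TestResult(statistic=0.0, df=0, p=1.0, method="pearson")
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - exp) ** 2 / exp).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)),
                      method="pearson")


def freeman_halton(table) -> TestResult:
    """Fisher-Freeman-Halton exact test for r x c tables (Monte Carlo
    via scipy's network algorithm for 2x2; permutation otherwise)."""
    t = np.asarray(table, int)
    if t.shape == (2, 2):
        return fisher_exact(t)
    res = stats.chi2_contingency(t, correction=False)
    # exact enumeration is combinatorial; use the conditional Monte Carlo
    rng = np.random.default_rng(0)
    rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
    obs = res.statistic
    hits = 0
    reps = 10000
    for _ in range(reps):
        perm = rng.permutation(cols)
        sim = np.zeros_like(t)
        np.add.at(sim, (rows, perm), 1)
        exp = np.outer(sim.sum(axis=1), sim.sum(axis=0)) / sim.sum()
        stat = ((sim - exp) ** 2 / exp).sum()
        hits += stat >= obs - 1e-12
    return TestResult(statistic=float(obs), df=None, p=(hits + 1) / (reps + 1),
                      method="freeman-halton-mc")


def odds_ratio_wald(table) -> OrResult:
    """OR = ad/bc with Wald CI exp(ln OR +/- 1.96 SE); Haldane 0.5
    correction (flagged) when any cell is zero."""
    t = _as_2x2(table)
    corrected = (t == 0).any()
    if corrected:
        t = t + 0.5
    a, b, c, d = t.ravel()
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = abs(np.log(or_)) / se
    return OrResult(
        odds_ratio=float(or_),
        ci_low=float(or_ * np.exp(-_Z95 * se)),
        ci_high=float(or_ * np.exp(_Z95 * se)),
        p=float(2 * stats.norm.sf(z)),
        corrected=bool(corrected),
    )


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U: exact enumeration for n1+n2 <= 12 without ties,
    otherwise normal approximation with continuity and tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    small = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if small else "asymptotic")
    u = float(res.statistic)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return TestResult(statistic=u, df=None, p=float(res.pvalue),
                      method="mwu-exact" if small else "mwu")


def group_compare(values, labels) -> TestResult:
    """Shapiro-Wilk gate (alpha 0.05 per group) -> pooled t-test if both
    groups look normal, Mann-Whitney U otherwise."""
    v = np.asarray(values, float)
    lab = np.asarray(labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    g1, g2 = v[lab == groups[0]], v[lab == groups[1]]
    if min(len(g1), len(g2)) < 3:
        warnings.warn("fewer than 3 per group; defaulting to Mann-Whitney U")
        return mann_whitney_u(g1, g2)
    normal = all(stats.shapiro(g).pvalue > 0.05 for g in (g1, g2))
    if normal:
        res = stats.ttest_ind(g1, g2, equal_var=True)
        return TestResult(statistic=float(res.statistic),
                          df=float(len(g1) + len(g2) - 2),
                          p=float(res.pvalue), method="ttest")
    return mann_whitney_u(g1, g2)


def logistic_regression(X: pd.DataFrame, y, mode: str = "multivariable") -> pd.DataFrame:
    """Univariable (per predictor) or multivariable logistic regression.

    Returns a frame with coefficient, OR, Wald 95% CI (z = 1.96) and p
    per predictor.  Separation is flagged; rank deficiency raises naming
    the collinear columns.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary")
    y01 = (y == y.max()).astype(float)

    if mode == "univariate":
        rows = [
            logistic_regression(X[[col]], y01, mode="multivariable").iloc[0]
            for col in X.columns
        ]
        return pd.DataFrame(rows)
    if mode != "multivariable":
        raise ValueError("mode must be 'univariate' or 'multivariable'")

    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; collinear columns near {worst}")

    Xc = sm.add_constant(X, has_constant="add")
    res = sm.GLM(y01, Xc, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    coefs = res.params
    ses = res.bse
    separated = bool(np.abs(coefs.drop("const")).max() > 50) if len(coefs) > 1 else False
    if separated:
        warnings.warn("possible separation: very large coefficients")
    rows = []
    for name in X.columns:
        b, se = coefs[name], ses[name]
        z = b / se if se > 0 else np.inf
        rows.append({
            "predictor": name, "coef": float(b), "or": float(np.exp(b)),
            "ci_low": float(np.exp(b - _Z95 * se)),
            "ci_high": float(np.exp(b + _Z95 * se)),
            "p": float(2 * stats.norm.sf(abs(z))),
            "separation_flag": separated,
        })
    return pd.DataFrame(rows).set_index("predictor").reset_index()


def table_one(df: pd.DataFrame, label_col: str = "label",
              continuous: list[str] | None = None,
              categorical: list[str] | None = None) -> pd.DataFrame:
    """Baseline-characteristics table: group comparison per covariate
    with the method tag recorded (t / MWU / pearson / yates / fisher)."""
    labels = df[label_col]
    groups = sorted(labels.unique())
    continuous = continuous or [c for c in df.columns
                                if c != label_col and df[c].dtype.kind == "f"]
    categorical = categorical or [c for c in df.columns
                                  if c != label_col and c not in continuous]
    rows = []
    for col in continuous:
        res = group_compare(df[col], labels)
        rows.append({"covariate": col, "statistic": res.statistic,
                     "method": res.method, "p": res.p})
    for col in categorical:
        tab = pd.crosstab(df[col], labels)
        if tab.shape == (2, 2) and (tab.to_numpy().sum(axis=0) > 0).all() \
                and (tab.to_numpy().sum(axis=1) > 0).all():
            res = chi2_dispatch(tab.to_numpy())
        else:
            res = rxc_chi2(tab.to_numpy())
        rows.append({"covariate": col, "statistic": res.statistic,
                     "method": res.method, "p": res.p})
    return pd.DataFrame(rows)
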