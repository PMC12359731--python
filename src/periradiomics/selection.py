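"""Three-stage radiomics feature reduction and Radscore construction.

Stage 1 -- stability: features whose inter-rater ICC(2,1) (two-way random
effects, absolute agreement, single rater) falls below a threshold
(default 0.75, conventional "good" reliability) are discarded.

Stage 2 -- redundancy: greedy minimum-redundancy maximum-relevance (mRMR,
MID scheme) ranks the survivors; relevance is the one-way ANOVA
F-statistic of feature vs class and redundancy the mean absolute Pearson
correlation with already-selected features.

Stage 3 -- sparsity: L1-penalized logistic regression (LASSO) over a
log-spaced penalty path, the penalty chosen by 10-fold cross-validated
binomial deviance (minimum rule by default, one-standard-error rule
available).  The Radscore of a case is the fitted model's predicted
probability (the linear predictor is also exposed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SelectionConfig",
    "RadscoreModel",
    "icc_2_1",
    "stability_filter",
    "mrmr_select",
    "lasso_cv",
    "radscore",
    "stratified_folds",
]


@dataclass
class SelectionConfig:
    icc_threshold: float = 0.75
    mrmr_keep: int = 30
    lasso_folds: int = 10
    lambda_rule: str = "min"     # or "1se"
    n_lambda: int = 40
    lambda_min_ratio: float = 1e-3
    standardize: bool = True
    correlation_prefilter: float | None = None  # drop one of any pair with |r| above
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.icc_threshold <= 1:
            raise ValueError("icc_threshold must be in (0, 1]")
        if self.lasso_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.mrmr_keep < 1:
            raise ValueError("mrmr_keep must be >= 1")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is n_subjects x k_raters.  A matrix with zero total
    variance (identical constants) returns 1.0 by convention.
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return 1.0
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    ssr = k * np.sum((row_mean - grand) ** 2)
    ssc = n * np.sum((col_mean - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0
    return float((msr - mse) / denom)


def stability_filter(features_rater1: pd.DataFrame, features_rater2: pd.DataFrame,
                     threshold: float = 0.75) -> list[str]:
    """Keep features with inter-rater ICC(2,1) >= threshold."""
    if not features_rater1.index.equals(features_rater2.index):
        raise ValueError("rater tables have misaligned case ids")
    common = [c for c in features_rater1.columns if c in features_rater2.columns]
    kept = []
    for col in common:
        icc = icc_2_1(np.column_stack([features_rater1[col], features_rater2[col]]))
        if icc >= threshold:
            kept.append(col)
    return kept


def mrmr_select(X: pd.DataFrame, y, k: int) -> list[str]:
    """Greedy mRMR (MID scheme): score = relevance - redundancy.

    Relevance is the class-association F-statistic mapped to the
    point-biserial correlation scale, ``sqrt(F / (F + n - 2))``, so it is
    commensurate with the redundancy term (mean absolute Pearson
    correlation with the already-selected features); a raw F-statistic
    would dwarf the redundancy penalty and never discard duplicates.
    Ties are broken by feature name order; constant columns rank last.
    Requesting more features than available returns them all with a
    warning.
    """
    X = X.copy()
    y = np.asarray(y)
    names = sorted(X.columns)
    if k > len(names):
        warnings.warn(f"k={k} exceeds {len(names)} candidate features; returning all")
        k = len(names)
    Z = X[names].to_numpy(float)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat, _ = f_classif(Z, y)
    fstat = np.nan_to_num(fstat, nan=0.0, posinf=np.finfo(float).max / 4)
    relevance = np.sqrt(fstat / (fstat + len(y) - 2))
    corr = np.abs(np.corrcoef(Z, rowvar=False))
    corr = np.nan_to_num(corr, nan=1.0)

    selected: list[int] = []
    remaining = list(range(len(names)))
    for _ in range(k):
        if not selected:
            scores = relevance[remaining]
        else:
            red = corr[np.ix_(remaining, selected)].mean(axis=1)
            scores = relevance[remaining] - red
        best = remaining[int(np.argmax(scores))]  # argmax takes first max => name order
        selected.append(best)
        remaining.remove(best)
    return [names[i] for i in selected]


def stratified_folds(case_ids, y, n_folds: int, seed: int) -> pd.Series:
    """Deterministic stratified fold assignment keyed by case id.

    Cases are sorted by id and shuffled within class with the seeded RNG,
    so the assignment is invariant to the input row order.
    """
    ids = pd.Index(case_ids)
    y = pd.Series(np.asarray(y), index=ids)
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=ids, dtype=int)
    start = 0  # offset classes so folds fill evenly overall
    for cls in np.unique(y):
        members = sorted(ids[y == cls])
        order = rng.permutation(len(members))
        for slot, idx in enumerate(order):
            fold[members[idx]] = (start + slot) % n_folds
        start += len(members)
    return fold


@dataclass
class RadscoreModel:
    """LASSO-selected radiomics signature.

    Coefficients are reported on the original feature scale; the Radscore
    is the predicted probability (inverse-logit of the linear predictor),
    consistent with reporting Radscores on a [0, 1] scale with
    probability-type cutoffs.
    """

    roi_kind: str
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_: float
    lambda_path: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    seed: int
    fold_assignment: dict | None = None

    def linear_predictor(self, features) -> np.ndarray:
        X = _to_matrix(features, self.feature_names)
        return self.intercept + X @ self.coefficients

    def predict(self, features) -> np.ndarray:
        return special.expit(self.linear_predictor(features))

    def to_json(self, path: str) -> None:
        payload = {
            "roi_kind": self.roi_kind,
            "feature_names": list(self.feature_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RadscoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            roi_kind=d["roi_kind"], feature_names=d["feature_names"],
            coefficients=np.asarray(d["coefficients"]), intercept=d["intercept"],
            lambda_=d["lambda"], lambda_path=np.array([]), cv_deviance=np.array([]),
            cv_deviance_se=np.array([]), seed=d["seed"],
        )


def _to_matrix(features, names) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise KeyError(f"missing selected features: {missing[:5]}")
        return features[list(names)].to_numpy(float)
    if isinstance(features, (dict, pd.Series)):
        try:
            return np.array([[float(features[n]) for n in names]])
        except KeyError as exc:
            raise KeyError(f"missing selected feature {exc}") from exc
    arr = np.atleast_2d(np.asarray(features, float))
    if arr.shape[1] != len(names):
        raise ValueError("feature matrix width does not match model")
    return arr


def radscore(model: RadscoreModel, features) -> np.ndarray | float:
    """Radscore = inverse-logit(intercept + sum coef * feature), in [0, 1]."""
    out = model.predict(features)
    return float(out[0]) if np.ndim(features) in (0, 1) or isinstance(features, (dict, pd.Series)) else out


# ---------------------------------------------------------------- LASSO ---

def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                 polish: bool = True) -> tuple[np.ndarray, float]:
    """Solve min (1/n) sum log(1+exp(-y' eta)) + lam * ||beta||_1.

    A liblinear fit locates the active set; with ``polish=True`` an
    L-BFGS pass on the active coordinates (signs fixed) then drives the
    KKT residuals to solver-independent precision.  CV path fits skip
    the polish: held-out deviance is insensitive to it.
    """
    n = len(y)
    C = 1.0 / (n * lam)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-8 if polish else 1e-5,
        max_iter=100000, intercept_scaling=1e4, random_state=0,
    )
    clf.fit(X, y)
    beta = clf.coef_.ravel().copy()
    b0 = float(clf.intercept_[0])
    if not polish:
        return beta, b0

    active = np.flatnonzero(beta)
    signs = np.sign(beta[active])

    def pack(theta):
        full = np.zeros(X.shape[1])
        full[active] = theta[1:]
        return theta[0], full

    def objective(theta):
        b0_, bet = pack(theta)
        eta = b0_ + X @ bet
        # smooth surrogate with fixed signs on the active set
        return float(np.mean(np.logaddexp(0, eta) - y * eta) + lam * np.sum(signs * theta[1:]))

    def grad(theta):
        b0_, bet = pack(theta)
        p = special.expit(b0_ + X @ bet)
        g0 = np.mean(p - y)
        g = X[:, active].T @ (p - y) / len(y) + lam * signs
        return np.concatenate([[g0], g])

    if len(active):
        theta0 = np.concatenate([[b0], beta[active]])
        res = optimize.minimize(objective, theta0, jac=grad, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10})
        b0_new, beta_new = pack(res.x)
        # keep the polish only if no sign flipped (active set confirmed)
        if np.all(np.sign(beta_new[active]) == signs):
            b0, beta = b0_new, beta_new
    else:
        prev = np.mean(y)
        b0 = float(special.logit(np.clip(prev, 1e-12, 1 - 1e-12)))
    return beta, b0


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_cv(X: pd.DataFrame, y, cfg: SelectionConfig | None = None,
             roi_kind: str = "GTV") -> RadscoreModel:
    """L1-penalized logistic regression with cross-validated penalty.

    Columns are standardized (mean 0, sd 1) before penalization and the
    returned coefficients are mapped back to the original feature scale.
    Constant columns are dropped with a warning; a single-class outcome
    is an error.
    """
    cfg = cfg or SelectionConfig()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float),
                         columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    y_arr = np.asarray(y, float)
    classes = np.unique(y_arr)
    if len(classes) < 2:
        raise ValueError("outcome has a single class")
    y_ser = pd.Series((y_arr == classes.max()).astype(float), index=X.index)
    # canonical row order: the fit is then exactly invariant to how the
    # caller happened to order the cases
    X = X.sort_index()
    y01 = y_ser.loc[X.index].to_numpy()

    sd = X.std(axis=0, ddof=0)
    const = sd[sd == 0].index.tolist()
    if const:
        warnings.warn(f"dropping constant columns: {const[:5]}")
        X = X.drop(columns=const)
        sd = sd.drop(const)
    names = list(X.columns)
    mu = X.mean(axis=0)
    Z = ((X - mu) / sd).to_numpy(float) if cfg.standardize else X.to_numpy(float)

    n = len(y01)
    prev = y01.mean()
    lam_max = float(np.max(np.abs(Z.T @ (y01 - prev))) / n)
    lambdas = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)

    folds = stratified_folds(X.index, y01, cfg.lasso_folds, cfg.seed)
    fold_arr = folds.loc[X.index].to_numpy()

    dev = np.zeros((cfg.n_lambda, cfg.lasso_folds))
    for f in range(cfg.lasso_folds):
        tr = fold_arr != f
        te = ~tr
        if y01[tr].min() == y01[tr].max() or te.sum() == 0:
            dev[:, f] = np.nan
            continue
        for li, lam in enumerate(lambdas):
            beta, b0 = _l1_logistic(Z[tr], y01[tr], lam, polish=False)
            p = special.expit(b0 + Z[te] @ beta)
            dev[li, f] = _binomial_deviance(y01[te], p)
    mean_dev = np.nanmean(dev, axis=1)
    se_dev = np.nanstd(dev, axis=1, ddof=1) / np.sqrt(np.sum(~np.isnan(dev), axis=1))

    best = int(np.nanargmin(mean_dev))
    if cfg.lambda_rule == "1se":
        limit = mean_dev[best] + se_dev[best]
        ok = np.flatnonzero(mean_dev <= limit)
        best = int(ok[0])  # largest lambda within one SE (path is decreasing)
    lam = float(lambdas[best])

    beta_std, b0 = _l1_logistic(Z, y01, lam)
    if cfg.standardize:
        coef = beta_std / sd.to_numpy()
        intercept = b0 - float(np.sum(beta_std * (mu / sd).to_numpy()))
    else:
        coef, intercept = beta_std, b0

    keep = np.flatnonzero(beta_std)
    return RadscoreModel(
        roi_kind=roi_kind,
        feature_names=[names[i] for i in keep],
        coefficients=coef[keep],
        intercept=float(intercept),
        lambda_=lam,
        lambda_path=lambdas,
        cv_deviance=mean_dev,
        cv_deviance_se=se_dev,
        seed=cfg.seed,
        fold_assignment=folds.to_dict(),
    )
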