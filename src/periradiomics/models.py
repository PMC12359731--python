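"""The four isolated predictive models and their cross-validation.

To avoid multicollinearity between radiomic and morphological predictors
the four models are deliberately kept in separate frameworks:

* ``CTfeatures`` -- logistic regression on maximum diameter + vessel
  convergence sign (VCS) only;
* ``GTV`` / ``GPTV`` / ``GPR`` -- logistic regression on that single
  Radscore only.

Fitting is maximum likelihood via iteratively reweighted least squares
(statsmodels GLM); complete separation triggers a flagged ridge-penalized
fallback.  Both apparent (resubstitution) and stratified out-of-fold
probabilities are produced and labeled distinctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .selection import stratified_folds

__all__ = ["PredictiveModel", "fit_logistic", "fit_ct_model", "fit_radscore_model",
           "crossvalidate"]

POSITIVE_CLASS = "IAC"


@dataclass
class PredictiveModel:
    name: str
    predictors: list[str]
    coefficients: np.ndarray
    intercept: float
    fitted_probabilities: pd.Series
    separation_flag: bool = False
    cov_params: np.ndarray | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.predictors].to_numpy(float)
        eta = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def _as_binary(labels) -> np.ndarray:
    y = pd.Series(labels)
    if y.dtype == object or y.dtype.name == "category":
        return (y == POSITIVE_CLASS).astype(float).to_numpy()
    return y.astype(float).to_numpy()


def fit_logistic(table: pd.DataFrame, predictors: list[str], label_col: str = "label",
                 name: str = "model") -> PredictiveModel:
    """ML logistic fit (IRLS); ridge fallback on separation, flagged."""
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    y = _as_binary(table[label_col])
    X = sm.add_constant(table[predictors].astype(float), has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        params = res.params.to_numpy()
        cov = res.cov_params().to_numpy()
        if np.abs(params).max() > 50:  # quasi-separation: runaway coefficients
            raise RuntimeError("separation suspected")
    except Exception:
        separated = True
        clf = LogisticRegression(C=1.0, max_iter=10000)
        clf.fit(table[predictors].to_numpy(float), y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        cov = None
        warnings.warn(f"{name}: separation detected; ridge-penalized fallback used")
    intercept, coef = float(params[0]), params[1:]
    eta = intercept + table[predictors].to_numpy(float) @ coef
    probs = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=table.index)
    return PredictiveModel(name=name, predictors=list(predictors), coefficients=coef,
                           intercept=intercept, fitted_probabilities=probs,
                           separation_flag=separated, cov_params=cov)


def fit_ct_model(table: pd.DataFrame, diameter_col: str = "max_diameter_mm",
                 vcs_col: str = "vcs", label_col: str = "label") -> PredictiveModel:
    """CT-features model: maximum diameter + VCS, nothing else."""
    return fit_logistic(table, [diameter_col, vcs_col], label_col, name="CTfeatures")


def fit_radscore_model(table: pd.DataFrame, radscore_col: str,
                       label_col: str = "label", name: str | None = None) -> PredictiveModel:
    """Radscore model: one Radscore column as the sole predictor."""
    return fit_logistic(table, [radscore_col], label_col,
                        name=name or radscore_col)


def crossvalidate(table: pd.DataFrame, predictors: list[str], label_col: str = "label",
                  folds: int = 10, seed: int = 0, max_retries: int = 20) -> pd.DataFrame:
    """Stratified out-of-fold probabilities; every case predicted once.

    Fold assignment depends on (seed, case id), not row order.  Folds
    whose training split lacks a class are re-drawn with a shifted seed,
    with an error after bounded retries.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = _as_binary(table[label_col])
    for attempt in range(max_retries):
        assign = stratified_folds(table.index, y, folds, seed + attempt)
        arr = assign.loc[table.index].to_numpy()
        ok = all(len(np.unique(y[arr != f])) == 2 for f in np.unique(arr))
        if ok:
            break
    else:
        raise RuntimeError("could not build folds with both classes in training data")

    out = pd.Series(np.nan, index=table.index)
    for f in np.unique(arr):
        tr, te = arr != f, arr == f
        model = fit_logistic(table.loc[tr], predictors, label_col)
        out.loc[te] = model.predict(table.loc[te])
    return pd.DataFrame({"fold": arr, "probability": out, "label": table[label_col]})
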