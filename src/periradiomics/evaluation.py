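"""Discrimination, calibration, and clinical-utility evaluation.

* ROC/AUC with the Mann-Whitney identity (ties counted 1/2), Youden-index
  cutoffs, DeLong structural-components variance and paired test,
  percentile-bootstrap confidence intervals with stratified resampling.
* Hosmer-Lemeshow calibration over deciles of risk (equal-count bins,
  ties kept together), df = bins - 2.
* Decision-curve analysis: net benefit
  ``NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t)`` against treat-all /
  treat-none references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "CalibrationResult",
    "DecisionCurve",
    "roc_auc",
    "delong_variance",
    "delong_test",
    "bootstrap_auc_ci",
    "youden_cutoff",
    "hosmer_lemeshow",
    "decision_curve",
    "compare_models",
]


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == object or y.dtype.kind in "US":
        y = (y == "IAC").astype(int)
    y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0/1 or MIA/IAC)")
    return y


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None
    ci_method: str | None = None
    youden_cutoff: float | None = None
    youden_sensitivity: float | None = None
    youden_specificity: float | None = None


@dataclass
class CalibrationResult:
    bin_counts: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def useful_range(self) -> tuple[float, float] | None:
        """The p_t interval where the model beats both references."""
        better = (self.net_benefit >= self.treat_all - 1e-12) & (self.net_benefit > 0)
        if not better.any():
            return None
        idx = np.flatnonzero(better)
        return float(self.thresholds[idx[0]]), float(self.thresholds[idx[-1]])


def roc_auc(scores, labels) -> RocResult:
    """Empirical ROC and AUC (trapezoidal = Mann-Whitney with ties at 1/2)."""
    y = _check_binary(labels)
    s = np.asarray(scores, float)
    n1, n0 = int(y.sum()), int((1 - y).sum())

    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    thr = np.unique(s)[::-1]  # predict positive if score >= threshold
    sens = np.array([(s[y == 1] >= t).mean() for t in thr])
    spec = np.array([(s[y == 0] < t).mean() for t in thr])

    j = sens + spec - 1
    best = np.flatnonzero(j == j.max())
    cut_idx = best[np.argmin(thr[best])]  # ties -> lowest threshold
    return RocResult(
        thresholds=thr, sensitivity=sens, specificity=spec, auc=float(auc),
        youden_cutoff=float(thr[cut_idx]),
        youden_sensitivity=float(sens[cut_idx]),
        youden_specificity=float(spec[cut_idx]),
    )


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (ties: lowest)."""
    return float(roc.youden_cutoff)


def _delong_components(scores: np.ndarray, y: np.ndarray):
    x, yneg = scores[y == 1], scores[y == 0]
    # psi(X_i, Y_j) = 1 if X>Y, 0.5 if tie, 0 otherwise
    cmp = (x[:, None] > yneg[None, :]).astype(float) + 0.5 * (x[:, None] == yneg[None, :])
    v10 = cmp.mean(axis=1)  # per positive case
    v01 = cmp.mean(axis=0)  # per negative case
    return v10, v01, cmp.mean()


def delong_variance(scores, labels) -> float:
    """DeLong structural-components variance of a single AUC."""
    y = _check_binary(labels)
    v10, v01, _ = _delong_components(np.asarray(scores, float), y)
    m, n = len(v10), len(v01)
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    if var <= 0:
        raise ValueError("degenerate DeLong variance (constant components); "
                         "scores may be perfectly separating or constant")
    return float(var)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for two correlated AUCs; returns (z, p two-sided)."""
    y = _check_binary(labels)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or len(a) != len(y):
        raise ValueError("paired scores must cover identical cases")
    v10a, v01a, auc_a = _delong_components(a, y)
    v10b, v01b, auc_b = _delong_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if auc_a == auc_b and var <= 0:
        return 0.0, 1.0
    if var <= 0:
        raise ValueError("degenerate DeLong variance in paired comparison")
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float]:
    """Wald CI from the DeLong variance, clipped to [0, 1]."""
    auc = roc_auc(scores, labels).auc
    se = np.sqrt(delong_variance(scores, labels))
    zq = stats.norm.ppf(1 - alpha / 2)
    return float(max(0.0, auc - zq * se)), float(min(1.0, auc + zq * se))


def bootstrap_auc_ci(scores, labels, reps: int = 2000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI with stratified case resampling."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    y = _check_binary(labels)
    s = np.asarray(scores, float)
    rng = np.random.default_rng(seed)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    aucs = np.empty(reps)
    for r in range(reps):
        bp = pos[rng.integers(0, n1, n1)]
        bn = neg[rng.integers(0, n0, n0)]
        ranks = stats.rankdata(np.concatenate([bp, bn]))
        aucs[r] = (ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def hosmer_lemeshow(probabilities, labels, g: int = 10) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over deciles of risk.

    Equal-count bins with tied probabilities kept together; bins that
    collapse are merged with a warning (handled by qcut 'drop'); the
    statistic is ``sum (O-E)^2 / (E (1 - E/n_bin))`` with df = bins - 2.
    """
    if g < 3:
        raise ValueError("need at least 3 bins")
    y = _check_binary(labels)
    p = np.asarray(probabilities, float)
    bins = pd.qcut(p, g, duplicates="drop")
    grp = pd.DataFrame({"y": y, "p": p}).groupby(bins, observed=True)
    n_g = grp.size().to_numpy(float)
    obs = grp["y"].sum().to_numpy(float)
    exp = grp["p"].sum().to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / (exp * (1 - exp / n_g))
    terms = terms[np.isfinite(terms)]
    stat = float(terms.sum())
    df = max(int(len(n_g) - 2), 1)
    return CalibrationResult(
        bin_counts=n_g, observed=obs, expected=exp,
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)),
    )


def decision_curve(probabilities, labels, thresholds=None) -> DecisionCurve:
    """Net benefit of treating according to model probability >= p_t."""
    y = _check_binary(labels)
    p = np.asarray(probabilities, float)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    pt = np.asarray(thresholds, float)
    if ((pt <= 0) | (pt >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    odds = pt / (1 - pt)
    nb = np.empty_like(pt)
    for i, t in enumerate(pt):
        pred = p >= t
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[i] = tp - fp * odds[i]
    treat_all = prev - (1 - prev) * odds
    return DecisionCurve(thresholds=pt, net_benefit=nb, treat_all=treat_all,
                         treat_none=np.zeros_like(pt))


def compare_models(model_scores: dict[str, np.ndarray], labels,
                   order: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Pairwise DeLong comparison table (z, p) across models on one cohort."""
    names = list(model_scores)
    lengths = {len(np.asarray(v)) for v in model_scores.values()}
    if len(lengths) != 1 or lengths.pop() != len(np.asarray(labels)):
        raise ValueError("all models must score the identical case set")
    pairs = order or [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        z, p = delong_test(model_scores[a], model_scores[b], labels)
        rows.append({"model_a": a, "model_b": b, "z": z, "p": p})
    return pd.DataFrame(rows)
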