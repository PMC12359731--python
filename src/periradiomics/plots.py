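"""ROC, calibration, and decision-curve plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import DecisionCurve, RocResult

__all__ = ["plot_roc", "plot_calibration", "plot_decision_curves"]


def plot_roc(rocs: dict[str, RocResult], path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in rocs.items():
        ax.plot(1 - r.specificity, r.sensitivity, label=f"{name} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration(probabilities: dict[str, np.ndarray], labels, path: str,
                     bins: int = 10) -> None:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "IAC").astype(float)
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, p in probabilities.items():
        p = np.asarray(p, float)
        edges = np.quantile(p, np.linspace(0, 1, bins + 1))
        idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, bins - 1)
        obs = [y[idx == b].mean() for b in range(bins) if (idx == b).any()]
        exp = [p[idx == b].mean() for b in range(bins) if (idx == b).any()]
        ax.plot(exp, obs, "o-", ms=3, label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Observed fraction")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decision_curves(curves: dict[str, DecisionCurve], path: str) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    first = next(iter(curves.values()))
    ax.plot(first.thresholds, first.treat_all, color="gray", lw=1, label="treat all")
    ax.plot(first.thresholds, first.treat_none, color="black", lw=1, label="treat none")
    for name, c in curves.items():
        ax.plot(c.thresholds, c.net_benefit, label=name)
    ax.set_ylim(bottom=-0.1)
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
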