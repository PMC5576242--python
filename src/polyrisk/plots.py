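"""Figures for the evaluation layer: ROC curves, score densities, decile ORs."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_roc", "plot_score_density", "plot_decile_or"]


def plot_roc(scores, labels, ax=None, label=None):
    """Empirical ROC curve of a risk score against 0-1 status."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tpr = np.concatenate([[0.0], np.cumsum(y == 1) / max((y == 1).sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(y == 0) / max((y == 0).sum(), 1)])
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend()
    return ax


def plot_score_density(scores, labels, ax=None, bins=40):
    """Risk-score distributions of cases vs controls (normalized histograms)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(s[y == 0], bins=bins, density=True, alpha=0.5, label="controls")
    ax.hist(s[y == 1], bins=bins, density=True, alpha=0.5, label="cases")
    ax.set_xlabel("genomic risk score")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_decile_or(table, ax=None):
    """Bar chart of decile odds ratios with CI whiskers (lowest decile = 1)."""
    if ax is None:
        _, ax = plt.subplots()
    x = table["decile"].to_numpy()
    orr = table["odds_ratio"].to_numpy(dtype=float)
    ax.bar(x, orr, color="#4878d0")
    if {"ci_low", "ci_high"} <= set(table.columns):
        err = np.vstack([orr - table["ci_low"], table["ci_high"] - orr])
        ax.errorbar(x, orr, yerr=np.clip(err, 0, None), fmt="none", ecolor="k", capsize=2)
    ax.set_xlabel("risk score decile")
    ax.set_ylabel("odds ratio vs lowest decile")
    return ax
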