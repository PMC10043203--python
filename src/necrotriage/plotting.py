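"""Plots: importance histograms, ROC curves, prefix-sweep traces."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt

from .importance import ImportanceTable
from .metrics import roc_auc, roc_points

__all__ = ["plot_importance", "plot_roc", "plot_prefix_trace"]


def plot_importance(table: ImportanceTable, top: int | None = None, ax=None):
    """Descending-importance histogram (one bar per feature)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    ranking = table.ranking if top is None else table.top(top)
    means = dict(zip(table.feature_ids, table.mean_importance))
    names = [table.catalog.name_of(f) for f in ranking]
    ax.bar(range(len(ranking)), [means[f] for f in ranking])
    ax.set_xticks(range(len(ranking)))
    ax.set_xticklabels(names, rotation=75, ha="right", fontsize=7)
    ax.set_ylabel("mean Gini importance")
    ax.figure.tight_layout()
    return ax


def plot_roc(truth, scores, ax=None):
    """ROC curve of the minority (necrosis) class with its AUC."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    fpr, tpr, _ = roc_points(truth, scores)
    auc = roc_auc(truth, scores)
    ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity (minority as positive)")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax


def plot_prefix_trace(trace: Sequence[tuple[int, float]], metric: str = "auc", ax=None):
    """Metric vs number of top-ranked features (the FC_k sweep)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ks = [k for k, _ in trace]
    vals = [v for _, v in trace]
    ax.plot(ks, vals, marker="o")
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel(metric.upper())
    return ax
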