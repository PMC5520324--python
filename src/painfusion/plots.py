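"""Plain matplotlib renderings of the pipeline's diagnostic figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram


def plot_dendrogram(solution, path, max_leaves=30):
    """Truncated dendrogram of the Ward merge history."""
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(solution.merge_history, truncate_mode="lastp", p=max_leaves,
               no_labels=True, ax=ax)
    ax.set_ylabel("Ward distance")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_roc(roc, path, label=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc["fpr"], roc["tpr"],
            label=f"AUC = {roc['auc']:.2f}" if roc["auc"] else None)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    if label:
        ax.set_title(label)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_obs_vs_pred_hist(observed, predicted, path, bins=None, label=None):
    """Side-by-side histograms of observed and predicted values."""
    if bins is None:
        bins = np.linspace(0, 10, 11)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(observed, bins=bins, alpha=0.6, label="observed", density=True)
    ax.hist(predicted, bins=bins, alpha=0.6, label="predicted", density=True)
    ax.set_ylabel("share of patients")
    if label:
        ax.set_title(label)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
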