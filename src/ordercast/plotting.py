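"""Seaborn-based report figures (confusion matrix, correlation heatmap)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import seaborn as sns


def plot_confusion(confusion, ax=None):
    """Annotated heatmap of a binary confusion matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    sns.heatmap(confusion.as_array(), annot=True, fmt="d", cbar=False,
                xticklabels=["partial", "entire"],
                yticklabels=["partial", "entire"], ax=ax, cmap="Blues")
    ax.set_xlabel("Predicted")
    ax.set_ylabel("Actual")
    ax.set_title("Held-out confusion matrix")
    return ax


def plot_correlations(table, ax=None):
    """Annotated heatmap of the Pearson correlation table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sns.heatmap(table, annot=True, fmt=".2f", vmin=-1, vmax=1,
                cmap="coolwarm", ax=ax)
    ax.set_title("Pearson correlations")
    return ax
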