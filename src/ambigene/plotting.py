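"""Figure helpers: abundance barplots and misclassification violin plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io_design import StackedCounts

__all__ = ["plot_mean_count_barplot", "plot_misclassification_violin"]


def plot_mean_count_barplot(stacked: StackedCounts, exclude_genes=None,
                            path=None, ax=None):
    """Mean count per mapper, with and without a gene subset excluded.

    Mirrors the style of per-mapper abundance barplots: one bar pair per
    mapper (all genes vs the set with ``exclude_genes`` removed).
    """
    exclude = set(exclude_genes or [])
    keep_mask = np.array([g not in exclude for g in stacked.gene_ids])
    mappers = stacked.mappers
    all_means, kept_means = [], []
    for m in mappers:
        cols = stacked.mapper_labels == m
        all_means.append(stacked.counts[:, cols].mean())
        kept_means.append(stacked.counts[np.ix_(keep_mask, cols)].mean()
                          if keep_mask.any() else 0.0)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(mappers))
    ax.bar(x - 0.2, all_means, width=0.4, label="all genes")
    ax.bar(x + 0.2, kept_means, width=0.4, label="excluding DGs")
    ax.set_xticks(x, mappers)
    ax.set_ylabel("mean count")
    ax.legend()
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_misclassification_violin(reports, path=None, ax=None):
    """Violin plot of per-repeat misclassification % for several reports.

    ``reports`` is a mapping label -> ClassifierReport.
    """
    labels = list(reports)
    data = [np.asarray(reports[k].misclassification_pct) for k in labels]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * max(4, len(labels)), 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(np.arange(1, len(labels) + 1), labels, rotation=45,
                  ha="right")
    ax.set_ylabel("misclassified samples (%)")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
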