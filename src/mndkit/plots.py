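"""Simple reproducible plots for MND and delta-MND distributions.

Deliberately plain matplotlib output (boxplots with jittered points); no
publication styling.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless by default
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError


def _grouped_box(values_by_group: dict[str, np.ndarray], ylabel: str, title: str):
    if not values_by_group:
        raise ValidationError("nothing to plot")
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(values_by_group), 4))
    labels = list(values_by_group)
    data = [values_by_group[k] for k in labels]
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    rng = np.random.default_rng(0)  # fixed jitter: identical output every run
    for i, vals in enumerate(data, start=1):
        x = i + rng.uniform(-0.15, 0.15, size=len(vals))
        ax.plot(x, vals, "o", markersize=3, alpha=0.5)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_mnd_by_group(
    mnd_table: pd.DataFrame,
    grouping: pd.DataFrame,
    gene_set: str,
    out: str | Path | None = None,
):
    """Boxplot of per-sample mean MND by group for one gene set."""
    sub = mnd_table[mnd_table["gene_set"] == gene_set].merge(
        grouping, on="sample_id"
    )
    groups = {
        str(label): part["mean_mnd"].to_numpy()
        for label, part in sub.groupby("group", sort=True)
    }
    fig = _grouped_box(groups, "mean MND", gene_set)
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_delta_by_cohort(
    delta_table: pd.DataFrame, gene_set: str, out: str | Path | None = None
):
    """Boxplot of delta-MND by cohort for one gene set."""
    sub = delta_table[delta_table["gene_set"] == gene_set]
    groups = {
        str(label) or "(all)": part["delta"].to_numpy()
        for label, part in sub.groupby("cohort", sort=True)
    }
    fig = _grouped_box(groups, "delta MND", gene_set)
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
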