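"""Simple score-distribution plot (one panel, violins per region/class)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .defaults import REGION_ORDER

_CLASS_COLORS = {"benign": "#8fd18f", "vus": "#9ecae1", "pathogenic": "#f08080"}


def plot_region_scores(df: pd.DataFrame, ax=None):
    """Violin plot of scores per region, split by clinical class."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(12, 5))
    else:
        fig = ax.figure
    width = 0.28
    for ci, cls in enumerate(("benign", "vus", "pathogenic")):
        positions, data = [], []
        for ri, region in enumerate(REGION_ORDER):
            scores = df.loc[
                (df["region"] == region) & (df["clin_class"] == cls), "score"
            ].to_numpy()
            if len(scores) >= 2:
                positions.append(ri + (ci - 1) * width)
                data.append(scores)
        if data:
            parts = ax.violinplot(data, positions=positions, widths=width, showmedians=True)
            for body in parts["bodies"]:
                body.set_facecolor(_CLASS_COLORS[cls])
                body.set_alpha(0.7)
    ax.set_xticks(range(len(REGION_ORDER)))
    ax.set_xticklabels(REGION_ORDER, rotation=30, ha="right")
    ax.set_ylabel("Phred-scaled score")
    handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in _CLASS_COLORS.values()]
    ax.legend(handles, list(_CLASS_COLORS), frameon=False)
    fig.tight_layout()
    return fig
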