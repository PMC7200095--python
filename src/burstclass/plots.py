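"""Validation figures: diel composition bars, cluster/speed panels, actograms."""
from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .field_validation import ActogramGrid, CompositionTable


def plot_composition(table: CompositionTable, path=None):
    """Stacked behaviour-proportion bars per time-of-day bin, one panel per month."""
    props = table.proportions()
    months = props.index.get_level_values(0).unique()
    fig, axes = plt.subplots(len(months), 1,
                             figsize=(10, 2.2 * max(len(months), 1)),
                             squeeze=False)
    for ax, month in zip(axes[:, 0], months):
        sub = props.loc[month]
        bottom = np.zeros(len(sub))
        for cls in sub.columns:
            ax.bar(sub.index, sub[cls].to_numpy(), width=sub.index[1] - sub.index[0]
                   if len(sub) > 1 else 30, bottom=bottom, label=cls, align="edge")
            bottom += sub[cls].fillna(0).to_numpy()
        flag = " (insufficient days)" if month in table.flagged_months else ""
        ax.set_title(f"{month}{flag}", fontsize=9)
        ax.set_xlim(0, 1440)
        ax.set_ylim(0, 1)
    axes[0, 0].legend(fontsize=7, ncol=3)
    axes[-1, 0].set_xlabel("minute of day (UTC)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_cluster_speed(coherence: dict[str, float], matched: pd.DataFrame,
                       path=None):
    """Left: in-cluster proportion per behaviour; right: matched-speed boxplots."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    names = list(coherence)
    ax1.bar(names, [coherence[c] for c in names])
    ax1.set_ylabel("proportion of assignments in a GPS cluster")
    ax1.tick_params(axis="x", rotation=45)
    groups = [g["speed"].to_numpy() for _, g in matched.groupby("behaviour")]
    labels = [k for k, _ in matched.groupby("behaviour")]
    if groups:
        ax2.boxplot(groups, tick_labels=labels)
    ax2.set_ylabel("GPS speed (m/s)")
    ax2.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_actogram(grid: ActogramGrid, path=None, title: str = ""):
    """Day-by-time raster (darker = higher value) with sun-event overlays."""
    fig, ax = plt.subplots(figsize=(10, max(2, 0.12 * len(grid.days))))
    ax.imshow(grid.values, aspect="auto", cmap="Greys", origin="upper",
              extent=(0, 1440, len(grid.days), 0))
    if grid.sun_events:
        for i, (rise, sset) in enumerate(grid.sun_events):
            for minute in (rise, sset):
                if minute is not None:
                    ax.plot([minute, minute], [i, i + 1], color="red", lw=1)
    ax.set_xlabel("minute of day (UTC)")
    ax.set_ylabel("day")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
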