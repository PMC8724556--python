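"""Static plot exports: response curves, feature boxplots, heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .quantify import HeatmapMatrix


def plot_response_curves(curves: pd.DataFrame, path=None):
    """Mean ± sd live-fraction (or ratio) vs day, one line per condition."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, grp in curves.groupby("condition"):
        grp = grp.sort_values("day")
        ax.errorbar(grp["day"], grp["mean"], yerr=grp["sd"], marker="o",
                    capsize=3, label=str(cond))
    mode = curves["mode"].iloc[0] if len(curves) else "proportion"
    norm = bool(curves["normalized"].iloc[0]) if len(curves) else False
    ax.set_xlabel("day")
    ax.set_ylabel(("normalized " if norm else "") + f"live {mode}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_feature_boxplots(calls: pd.DataFrame, features: pd.DataFrame,
                          feature: str, path=None):
    """Per-day boxplots of one feature split by live/dead class."""
    merged = calls.merge(features, on=["well", "day", "roi_id"])
    days = sorted(merged["day"].unique())
    fig, ax = plt.subplots(figsize=(6, 4))
    data, positions, colors = [], [], []
    for i, day in enumerate(days):
        for j, (cls, color) in enumerate((("live", "tab:blue"), ("dead", "tab:orange"))):
            vals = merged.loc[(merged["day"] == day) & (merged["label"] == cls), feature]
            data.append(vals.dropna().to_numpy())
            positions.append(i * 3 + j)
            colors.append(color)
    boxes = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
    for patch, color in zip(boxes["boxes"], colors):
        patch.set_facecolor(color)
    ax.set_xticks([i * 3 + 0.5 for i in range(len(days))], [f"d{d:g}" for d in days])
    ax.set_ylabel(feature)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_heatmap(hm: HeatmapMatrix, path=None):
    """Clustered row-z-scored heatmap."""
    ordered = hm.ordered()
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
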