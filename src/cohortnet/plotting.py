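"""Static summary plots: connectance heatmap, path-frequency bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends beforehand

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["connectance_heatmap", "path_frequency_barplot"]


def connectance_heatmap(cm: pd.DataFrame, ax=None):
    """Heatmap of the L x L connectance matrix with layer labels."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(cm.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(cm.columns)), cm.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.index)), cm.index)
    for i in range(len(cm.index)):
        for j in range(len(cm.columns)):
            ax.text(j, i, f"{cm.iloc[i, j]:.2f}", ha="center", va="center",
                    color="white", fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="weighted density")
    ax.set_title("Connectance within and between layers")
    return ax


def path_frequency_barplot(freqs: dict, ax=None, top: int = 20):
    """Bar chart of node path-appearance frequencies (descending)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    items = sorted(freqs.items(), key=lambda kv: -kv[1])[:top]
    ax.bar([str(k) for k, _ in items], [v for _, v in items])
    ax.set_ylabel("fraction of paths")
    ax.tick_params(axis="x", rotation=90)
    return ax
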