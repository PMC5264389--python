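"""Optional figures: centroid curves and the 3-D habituation space."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_centroids", "plot_habituation_space"]


def plot_centroids(centroids: pd.DataFrame, ax=None):
    """Plot labelled centroid curves (index = time_s, one column per label)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    styles = {"low_hab": "-", "mid_hab": "--", "high_hab": ":"}
    for col in centroids.columns:
        ax.plot(centroids.index, centroids[col], styles.get(col, "-"),
                color="black", label=col)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    return ax


def plot_habituation_space(space: pd.DataFrame, ax=None, annotate: bool = True):
    """3-D scatter of odorants at their median centroid distances."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
    ax.scatter(space["lowhab"], space["midhab"], space["highhab"], s=40)
    if annotate:
        for name, row in space.iterrows():
            ax.text(row["lowhab"], row["midhab"], row["highhab"], str(name), fontsize=7)
    ax.set_xlabel("distance to low hab")
    ax.set_ylabel("distance to mid hab")
    ax.set_zlabel("distance to high hab")
    return ax
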