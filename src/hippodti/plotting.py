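"""Minimal plot helpers for VOI feature scatter and cluster inspection."""

from __future__ import annotations

import numpy as np
import pandas as pd


def voi_scatter_3d(
    table: pd.DataFrame,
    dataset_label: str,
    features: tuple[str, str, str] = ("FA", "MD", "RD"),
    color_by: str = "layer",
    ax=None,
):
    """3D scatter of per-VOI metric triplets, coloured by layer or cluster.

    Returns the matplotlib Axes3D; creates a figure when ``ax`` is None.
    """
    import matplotlib.pyplot as plt

    sub = table[table["dataset_label"] == dataset_label]
    if ax is None:
        fig = plt.figure(figsize=(5, 4))
        ax = fig.add_subplot(111, projection="3d")
    for key, grp in sub.groupby(color_by):
        ax.scatter(grp[features[0]], grp[features[1]], grp[features[2]], label=str(key), s=18)
    ax.set_xlabel(features[0])
    ax.set_ylabel(features[1])
    ax.set_zlabel(features[2])
    ax.set_title(dataset_label)
    ax.legend(fontsize=7)
    return ax
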