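"""Optional matplotlib renderings of the report tables.

The analysis never depends on rendered figures; these helpers draw the
two standard views from the data files the pipeline emits.
"""

from __future__ import annotations

import numpy as np


def plot_disparity(disparity, ax=None):
    """Range plot: production score vs consumption-score mean and range,
    one row per country (most disparate production first)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 0.3 * len(disparity) + 1.5))
    df = disparity.sort_values("fmi_p", ascending=True)
    y = np.arange(len(df))
    for yi, (_, row) in zip(y, df.iterrows()):
        color = "firebrick" if row.percent_change > 0 else "seagreen"
        ax.plot([row.mean_fmi_c, row.fmi_p], [yi, yi], color=color, lw=3,
                alpha=0.6, zorder=1)
        ax.plot([row.min_fmi_c, row.max_fmi_c], [yi, yi], color="gray",
                lw=1, zorder=2)
    ax.scatter(df["fmi_p"], y, marker="s", color="k", zorder=3,
               label="production (FMI$_P$)")
    ax.scatter(df["mean_fmi_c"], y, marker="^", color="tab:blue", zorder=3,
               label="mean consumption (FMI$_C$)")
    ax.set_yticks(y, df["country_id"])
    ax.set_xlabel("management-intensity score")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_fmi_relationship(summary, derivations, ax=None):
    """Scatter of aggregate FMI_C vs FMI_P per derivation with the 1:1
    reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    for d in derivations:
        ax.scatter(summary["fmi_p"], summary[d], s=14, alpha=0.7, label=d)
    lim = [0, 1]
    ax.plot(lim, lim, "k-", lw=1, label="1:1")
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.set_xlabel("FMI$_P$ (production)")
    ax.set_ylabel("FMI$_C$ (consumption)")
    ax.legend(fontsize=8)
    return ax
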