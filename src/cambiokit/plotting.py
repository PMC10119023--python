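"""Figures: landmark-aligned sector bars and projection-stack profiles."""

from __future__ import annotations

from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .lineage_sectors import Sector, sector_plot_table
from .polar_projection import ProjectionStack

__all__ = ["plot_sector_bars", "plot_stack_profile"]


def plot_sector_bars(sectors: Iterable[Sector], ax: Optional[plt.Axes] = None):
    """Horizontal sector bars aligned at the landmark (vertical line at 0).

    Xylem extent plots to the left of the landmark line, phloem extent to
    the right; bars are coloured by sector class.
    """
    tab = sector_plot_table(sectors)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.18 * len(tab) + 1))
    for _, row in tab.iterrows():
        ax.barh(row["bar"], row["end"] - row["start"], left=row["start"],
                color=row["colour"], height=0.8, edgecolor="none")
    ax.axvline(0.0, color="gold", lw=2, zorder=3)
    ax.set_xlabel("cells from landmark (xylem side < 0 < phloem side)")
    ax.set_yticks([])
    ax.invert_yaxis()
    return ax


def plot_stack_profile(
    stack: ProjectionStack, channel: str, ax: Optional[plt.Axes] = None
):
    """Mean +/- sd radial profile of one channel, aligned at the landmark."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    k = stack.channels.index(channel)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(stack.mean[k], axis=0)
        sd = np.nanmean(stack.sd[k], axis=0)
    x = np.arange(len(mean)) - stack.reference_row
    ax.plot(x, mean, lw=1.5, label=channel)
    ax.fill_between(x, mean - sd, mean + sd, alpha=0.25, linewidth=0)
    ax.axvline(0.0, color="gold", lw=2)
    ax.set_xlabel("radial bins from landmark (xylem side < 0)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend(frameon=False)
    return ax
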