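"""Thin matplotlib rendering layer over the data exports.

Figures mirror the CSV writers one-to-one; nothing here computes model
quantities.
"""

from __future__ import annotations

import numpy as np

from .abm import ABMTimeSeries
from .equilibrium import BifurcationTable

__all__ = ["plot_bifurcation", "plot_heatmap", "plot_timeseries"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_bifurcation(table: BifurcationTable, ax=None):
    """Equilibrium larval density vs σ; stable branches solid markers,
    unstable branches open markers."""
    ax = _axes(ax)
    df = table.to_dataframe()
    for stability, marker in (("stable", "o"), ("unstable", "x"), ("marginal", "s")):
        sub = df[df["stability"] == stability]
        if len(sub):
            ax.plot(sub["sigma"], sub["L_star"], marker, ms=3, label=stability)
    ax.set_xlabel("release rate σ (males/day)")
    ax.set_ylabel("equilibrium larval density L*")
    ax.legend()
    return ax


def plot_heatmap(grid1, grid2, matrix: np.ndarray, ax=None, xlabel="", ylabel=""):
    ax = _axes(ax)
    im = ax.pcolormesh(grid1, grid2, matrix, shading="auto")
    ax.figure.colorbar(im, ax=ax)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax


def plot_timeseries(series: ABMTimeSeries, ax=None):
    ax = _axes(ax)
    for name in series.data:
        ax.plot(series.day, series[name], label=name)
    ax.set_xlabel("day")
    ax.set_ylabel("count")
    ax.legend(fontsize="small")
    return ax
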