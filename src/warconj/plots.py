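"""Matplotlib rendering of trajectories and sweep heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .simulate import Trajectory
from .sweeps import SweepGrid

__all__ = ["plot_trajectory", "plot_heatmap", "plot_1d_sweep"]

_STRAIN_STYLE = {
    "C1": ("attacker", "tab:blue"),
    "C2": ("target", "tab:orange"),
    "C3": ("transconjugant", "tab:green"),
}


def plot_trajectory(trajectory: Trajectory, ax=None, show_resources: bool = True):
    """Biomass (and optionally nutrient/toxin) time courses of one run."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, (label, color) in _STRAIN_STYLE.items():
        ax.plot(trajectory.times, trajectory.component(name), label=label, color=color)
    if show_resources:
        for name, style in (("N1", ":"), ("N2", "--"), ("N3", "-."), ("T", (0, (1, 1)))):
            series = trajectory.component(name)
            if np.any(series > 0):
                ax.plot(trajectory.times, series, linestyle=style, color="grey", label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("biomass / pool size")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_heatmap(grid: SweepGrid, value: str = "f_transconjugant", ax=None):
    """Heatmap of one endpoint quantity over a 2-D sweep grid."""
    if len(grid.axes) != 2:
        raise ValueError(f"heatmap needs a 2-D grid, got {len(grid.axes)} axis/axes")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x_axis, y_axis = grid.axes[1], grid.axes[0]
    data = grid.value_array(value)
    mesh = ax.pcolormesh(
        np.arange(len(x_axis) + 1), np.arange(len(y_axis) + 1), data,
        shading="flat", vmin=0.0, vmax=max(1.0, float(np.nanmax(data))),
    )
    ax.set_xticks(np.arange(len(x_axis)) + 0.5)
    ax.set_xticklabels([f"{v:.3g}" for v in x_axis.values], rotation=90, fontsize="x-small")
    ax.set_yticks(np.arange(len(y_axis)) + 0.5)
    ax.set_yticklabels([f"{v:.3g}" for v in y_axis.values], fontsize="x-small")
    ax.set_xlabel(x_axis.name)
    ax.set_ylabel(y_axis.name)
    plt.colorbar(mesh, ax=ax, label=value)
    return ax


def plot_1d_sweep(grid: SweepGrid, ax=None):
    """Final frequencies of all three strains along a 1-D sweep axis."""
    if len(grid.axes) != 1:
        raise ValueError(f"1-D sweep plot needs one axis, got {len(grid.axes)}")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    axis = grid.axes[0]
    for which, (label, color) in zip(
        ("f_attacker", "f_target", "f_transconjugant"), _STRAIN_STYLE.values()
    ):
        ax.plot(axis.values, grid.value_array(which), marker="o", ms=3,
                label=label, color=color)
    if axis.scale == "log":
        ax.set_xscale("log")
    ax.set_xlabel(axis.name)
    ax.set_ylabel("final frequency")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize="small")
    return ax
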