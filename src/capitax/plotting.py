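"""Figure helpers for density maps and speed/distance histograms."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt


def plot_density_map(grid, x_edges, y_edges, ax=None, cmap="viridis"):
    """Time-averaged cell-density colormap in assay coordinates (um)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    m = ax.pcolormesh(x_edges, y_edges, grid.T, cmap=cmap, shading="auto")
    ax.set_xlabel("axial distance d (um)")
    ax.set_ylabel("transverse distance (um)")
    ax.set_aspect("equal")
    plt.colorbar(m, ax=ax, label="cells um$^{-2}$ frame$^{-1}$")
    return ax


def plot_profile_fit(profile, fit, ax=None):
    """Accumulation profile histogram with its exponential fit overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = profile.bin_centers
    ax.bar(x, profile.density, width=np.diff(profile.bin_edges), alpha=0.5, label="data")
    xs = np.linspace(x.min(), x.max(), 300)
    ax.plot(xs, fit.predict(xs), "k-", label=f"fit, $\\lambda$ = {fit.lam:.0f} um")
    ax.set_xlabel("distance (um)")
    ax.set_ylabel("cell density (um$^{-2}$ frame$^{-1}$)")
    ax.legend()
    return ax


def plot_speed_heatmap(speed_profile, ax=None, cmap="magma"):
    """Relative frequency of speeds versus radial distance (heat map)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    m = ax.pcolormesh(
        speed_profile.radial_edges,
        speed_profile.speed_edges,
        speed_profile.frequencies,
        cmap=cmap,
        shading="auto",
    )
    ax.set_xlabel("radial distance r (um)")
    ax.set_ylabel("speed (um s$^{-1}$)")
    plt.colorbar(m, ax=ax, label="relative frequency")
    return ax
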