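"""Quick-look figures for pipeline output (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_tracks(tracks, geometry, ax=None, color_by_direction=True):
    """Overlay trajectories on the cell outline, colored by direction."""
    from .tracking import classify_direction

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cx, cy = geometry.center
    for radius in (geometry.cell_radius, geometry.csmac_radius):
        ax.add_patch(plt.Circle((cx, cy), radius, fill=False, ls="--", color="gray"))
    for t in tracks:
        c = "tab:green" if (
            color_by_direction and classify_direction(t, geometry) == "anterograde"
        ) else "tab:gray"
        ax.plot(t.x, t.y, lw=0.8, color=c)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    return ax


def plot_flow(field, geometry=None, ax=None, scale=None):
    """Quiver plot of one PIV flow field (nm/s)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.quiver(field.x, field.y, field.u, -field.v, angles="xy", scale=scale)
    if geometry is not None:
        cx, cy = geometry.center
        ax.add_patch(plt.Circle((cx, cy), geometry.cell_radius, fill=False, ls="--", color="gray"))
    ax.set_aspect("equal")
    ax.invert_yaxis()
    return ax


def plot_duration_distributions(outward, inward, ax=None):
    """Histogram + KDE curves of outward/inward run durations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for dist, label, color in ((outward, "outward", "tab:green"), (inward, "inward", "tab:gray")):
        if dist is None:
            continue
        centers = dist.bin_centers
        width = np.diff(dist.bin_edges)
        ax.bar(centers, dist.densities, width=width, alpha=0.3, color=color, label=label)
        ax.plot(centers, dist.kde_curve, color=color)
    ax.set_xlabel("run duration (s)")
    ax.set_ylabel("probability density")
    ax.legend()
    return ax
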