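"""Figure rendering: average/reconstructed thickness maps and polar
biomarker plots.

Rendered maps use the right-eye frame with nasal (+x) on the right and
superior (+y) up; mind this orientation when comparing against device
printouts, which may mirror left eyes.
"""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import EllipseSpec
from .zernike import CoefficientVector, reconstruct_values

__all__ = ["plot_map_pair", "plot_polar_biomarkers"]


def _grid_in_zone(zone_radius: float, n: int = 121):
    axis = np.linspace(-zone_radius, zone_radius, n)
    xx, yy = np.meshgrid(axis, axis)
    inside = np.hypot(xx, yy) <= zone_radius
    return xx, yy, inside


def plot_map_pair(mean_map_values, mean_map_xy, coeffs: CoefficientVector, path=None):
    """Side-by-side population-average map and its Zernike reconstruction."""
    x, y = mean_map_xy
    xx, yy, inside = _grid_in_zone(coeffs.zone_radius)
    recon = np.full(xx.shape, np.nan)
    recon[inside] = reconstruct_values(coeffs, xx[inside], yy[inside])

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), constrained_layout=True)
    sc = axes[0].scatter(x, y, c=mean_map_values, s=4, cmap="viridis")
    axes[0].set_title("population average (um)")
    im = axes[1].pcolormesh(xx, yy, recon, cmap="viridis", shading="auto")
    axes[1].set_title("Zernike reconstruction (um)")
    for ax, art in zip(axes, (sc, im)):
        ax.set_aspect("equal")
        ax.set_xlabel("nasal  x (mm)")
        ax.set_ylabel("superior  y (mm)")
        fig.colorbar(art, ax=ax, shrink=0.85)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _ellipse_path(e: EllipseSpec, n: int = 200):
    t = np.linspace(0, 2 * np.pi, n)
    a = math.radians(e.orientation_deg)
    u = e.semi_axes[0] * np.cos(t)
    v = e.semi_axes[1] * np.sin(t)
    x = e.center[0] + u * math.cos(a) - v * math.sin(a)
    y = e.center[1] + u * math.sin(a) + v * math.cos(a)
    return x, y


def plot_polar_biomarkers(points_xy, centroid_xy, data_ellipse: EllipseSpec,
                          centroid_ellipse: EllipseSpec, title="", path=None):
    """Polar-style scatter of per-eye biomarker vectors with both ellipses."""
    pts = np.asarray(points_xy, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5), constrained_layout=True)
    ax.scatter(pts[:, 0], pts[:, 1], s=10, color="gold", edgecolor="k",
               linewidths=0.2, label="eyes")
    ax.plot(*centroid_xy, marker="s", color="k", markersize=7, label="centroid")
    for e, color, label in ((data_ellipse, "tab:blue", "95% data ellipse"),
                            (centroid_ellipse, "tab:red", "95% centroid ellipse")):
        ex, ey = _ellipse_path(e)
        ax.plot(ex, ey, color=color, label=label)
    lim = max(np.abs(pts).max(), 1e-6) * 1.1
    for r_frac in (0.5, 1.0):
        circle = plt.Circle((0, 0), lim * r_frac, fill=False, ls=":", color="gray", lw=0.6)
        ax.add_patch(circle)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.legend(fontsize=8, loc="upper right")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
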