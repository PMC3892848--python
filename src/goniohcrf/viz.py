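"""Hemisphere visualization.

2D polar plots (view zenith as radius, view azimuth as angle), 3D
anisotropy surfaces, and principal-plane transects.  Plot orientation:
the principal plane is vertical with the backward-scattering half at the
top (sun at the bottom of the plot).  Interpolated fills are
presentation-only — all statistics elsewhere in the package operate on
the raw scheme nodes.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import griddata

from .hcrf import HemisphereDataset

__all__ = [
    "polar_to_xy",
    "interpolate_disk",
    "plot_hemisphere_2d",
    "plot_hemisphere_3d",
    "plot_pp_transect",
    "plot_drift_indicator",
]


def polar_to_xy(view_zenith: np.ndarray, view_azimuth: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Scheme position → plot coordinates (backward half up, radius = zenith)."""
    zen = np.asarray(view_zenith, float)
    az = np.radians(np.asarray(view_azimuth, float))
    return zen * np.sin(az), zen * np.cos(az)


def interpolate_disk(
    view_zenith: np.ndarray,
    view_azimuth: np.ndarray,
    values: np.ndarray,
    n_grid: int = 121,
    method: str = "linear",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scattered scheme values → regular grid over the view disk.

    Linear interpolation on the disk is exact at the scheme nodes; points
    outside the convex hull of the nodes are masked.
    """
    x, y = polar_to_xy(view_zenith, view_azimuth)
    r_max = float(np.max(view_zenith))
    gx, gy = np.meshgrid(np.linspace(-r_max, r_max, n_grid),
                         np.linspace(-r_max, r_max, n_grid))
    gz = griddata((x, y), values, (gx, gy), method=method)
    gz = np.ma.masked_invalid(np.where(gx**2 + gy**2 <= r_max**2, gz, np.nan))
    return gx, gy, gz


def _node_values(hem_or_arrays, values):
    if isinstance(hem_or_arrays, HemisphereDataset):
        zen = np.array([p.view_zenith for p in hem_or_arrays.positions])
        az = np.array([p.view_azimuth for p in hem_or_arrays.positions])
    else:
        zen, az = (np.asarray(a, float) for a in hem_or_arrays)
    values = np.asarray(values, float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("all values missing; nothing to plot")
    return zen[finite], az[finite], values[finite]


def plot_hemisphere_2d(
    hem_or_arrays,
    values: np.ndarray,
    path: str | Path | None = None,
    title: str = "",
    cmap: str = "viridis",
    levels: int = 21,
    method: str = "linear",
    show_nodes: bool = True,
):
    """Filled polar contour of a per-position field over the hemisphere.

    ``hem_or_arrays`` is a `HemisphereDataset` or a ``(zenith, azimuth)``
    array pair.  Returns the figure; saves a PNG/SVG when ``path`` given.
    """
    zen, az, vals = _node_values(hem_or_arrays, values)
    gx, gy, gz = interpolate_disk(zen, az, vals, method=method)
    fig, ax = plt.subplots(figsize=(6, 5.4))
    pcm = ax.contourf(gx, gy, gz, levels=levels, cmap=cmap)
    if show_nodes:
        x, y = polar_to_xy(zen, az)
        ax.plot(x, y, "k.", ms=3)
    r_max = float(np.max(zen))
    for ring in sorted(set(zen)):
        if ring > 0:
            ax.add_patch(plt.Circle((0, 0), ring, fill=False, color="0.6", lw=0.4))
    ax.annotate("backward (PP 0°)", (0, r_max), ha="center", va="bottom", fontsize=8)
    ax.annotate("forward (PP 180°)", (0, -r_max), ha="center", va="top", fontsize=8)
    ax.set_aspect("equal")
    ax.set_xlim(-r_max * 1.15, r_max * 1.15)
    ax.set_ylim(-r_max * 1.18, r_max * 1.18)
    ax.set_axis_off()
    fig.colorbar(pcm, ax=ax, shrink=0.85)
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150, metadata={})
        plt.close(fig)
    return fig


def plot_hemisphere_3d(
    hem_or_arrays,
    values: np.ndarray,
    path: str | Path | None = None,
    title: str = "",
    cmap: str = "viridis",
):
    """3D surface over the view disk with elevation = value."""
    zen, az, vals = _node_values(hem_or_arrays, values)
    x, y = polar_to_xy(zen, az)
    fig = plt.figure(figsize=(6.4, 5.2))
    ax = fig.add_subplot(projection="3d")
    ax.plot_trisurf(x, y, vals, cmap=cmap, linewidth=0.1)
    ax.set_xlabel("← forward   PP   backward →", fontsize=8)
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150, metadata={})
        plt.close(fig)
    return fig


def _pp_profile(hem: HemisphereDataset, values: np.ndarray,
                tolerance: float = 7.5) -> tuple[np.ndarray, np.ndarray]:
    """Signed view-zenith profile along the principal plane.

    Backward (azimuth ≈ 0°) positive, forward (≈ 180°) negative; nadir
    appears once at 0.
    """
    signed, vals = [], []
    for i, p in enumerate(hem.positions):
        if p.view_zenith == 0.0:
            signed.append(0.0)
            vals.append(values[i])
            continue
        d0 = abs((p.view_azimuth + 180.0) % 360.0 - 180.0)
        d180 = abs(p.view_azimuth - 180.0)
        if d0 <= tolerance:
            signed.append(p.view_zenith)
            vals.append(values[i])
        elif d180 <= tolerance:
            signed.append(-p.view_zenith)
            vals.append(values[i])
    order = np.argsort(signed)
    return np.asarray(signed)[order], np.asarray(vals)[order]


def plot_pp_transect(
    hem: HemisphereDataset,
    quantity: str = "hcrf",
    wavelengths: Sequence[float] = (549.0, 672.0, 864.0),
    path: str | Path | None = None,
):
    """Principal-plane transect: one curve per wavelength vs signed zenith."""
    if quantity == "hcrf":
        data = hem.hcrf
        ylabel = "HCRF"
    elif quantity == "anif":
        if hem.anif is None:
            raise ValueError("ANIF not computed on this dataset")
        data = hem.anif
        ylabel = "ANIF"
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    fig, ax = plt.subplots(figsize=(6.4, 4.2))
    for wl in wavelengths:
        j = int(np.argmin(np.abs(hem.wavelengths - wl)))
        xs, ys = _pp_profile(hem, data[:, j])
        ax.plot(xs, ys, "o-", ms=4, label=f"{hem.wavelengths[j]:.0f} nm")
    ax.axvline(0, color="0.8", lw=0.6)
    ax.set_xlabel("view zenith angle in principal plane (deg; backward positive)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=150, metadata={})
        plt.close(fig)
    return fig


def plot_drift_indicator(hem: HemisphereDataset, path: str | Path | None = None):
    """Polar plot of the per-position drift (interpolation-magnitude) indicator."""
    if hem.drift is None:
        raise ValueError("dataset carries no drift indicator")
    return plot_hemisphere_2d(hem, hem.drift, path=path,
                              title="drift indicator |mean c_diff − 1|",
                              cmap="magma")
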