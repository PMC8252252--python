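"""Plotting helpers: ERP profiles, trial rasters, and scalp topographies.

All functions draw onto a matplotlib Axes and are safe under the Agg
backend; the pipeline saves vector (SVG) output.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .erp import ErpProfile
from .montage import POSITIONS_2D


def plot_erp_profiles(ax, profiles: Sequence[ErpProfile], channel: str) -> None:
    """Overlay condition-average waveforms at one channel."""
    for prof in profiles:
        ax.plot(prof.times_ms, prof.channel(channel), label=f"{prof.condition} (n={prof.n_trials_used})")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (z)")
    ax.set_title(channel)
    ax.legend(frameon=False, fontsize=8)


def plot_erp_image(ax, image: np.ndarray, times_ms: np.ndarray, title: str = "") -> None:
    """Trials x time raster (already smoothed across neighboring trials)."""
    vmax = np.percentile(np.abs(image), 98) or 1.0
    ax.imshow(
        image,
        aspect="auto",
        origin="lower",
        extent=(times_ms[0], times_ms[-1], 0, image.shape[0]),
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
    )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("trial")
    ax.set_title(title)


def interpolate_topography(
    values: dict[str, float],
    grid_n: int = 64,
    power: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-distance-weighted interpolation of 8 electrode values onto
    a 2-D head grid (unit circle); returns (xx, yy, grid)."""
    labels = list(values)
    pos = np.array([POSITIONS_2D[lbl] for lbl in labels])
    vals = np.array([values[lbl] for lbl in labels], dtype=float)
    x = np.linspace(-1.0, 1.0, grid_n)
    xx, yy = np.meshgrid(x, x)
    grid = np.full_like(xx, np.nan)
    inside = xx**2 + yy**2 <= 1.0
    pts = np.stack([xx[inside], yy[inside]], axis=1)
    d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    w = d ** (-power)
    grid[inside] = (w @ vals) / w.sum(axis=1)
    return xx, yy, grid


def plot_topomap(ax, values: dict[str, float], title: str = "", vlim: Optional[float] = None) -> None:
    """8-electrode scalp map via inverse-distance interpolation."""
    xx, yy, grid = interpolate_topography(values)
    vmax = vlim if vlim is not None else np.nanmax(np.abs(grid)) or 1.0
    ax.pcolormesh(xx, yy, grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="auto")
    circle = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(circle), np.sin(circle), color="k", lw=1)
    for lbl, (px, py) in POSITIONS_2D.items():
        ax.plot(px, py, "k.", ms=3)
        ax.annotate(lbl, (px, py), fontsize=6, ha="center", va="bottom")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title, fontsize=9)
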