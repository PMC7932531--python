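"""Figure rendering: pressure maps, risk-region overlays, area box plots.

Colour semantics of the overlays follow the clinical convention used
throughout the package: yellow = R-ROI cells, white = cells with a
statistically significant pressure change between conditions, red = R-ROI
cells with no detected change.  A colourblind-safe alternative palette
(blue / white / orange) is available via ``palette="colorblind"``.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering only

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .gait import MeanPeakPressureMap
from .io import AreaTable
from .rroi import (
    CATEGORY_RROI_UNCHANGED,
    CATEGORY_SIG_DECREASE,
    CATEGORY_SIG_INCREASE,
    RedistributionMap,
    RROIMask,
)

__all__ = ["plot_mppm", "plot_rroi_overlay", "plot_redistribution", "plot_area_boxplot"]

_PALETTES = {
    "clinical": {"rroi": "yellow", "change": "white", "unchanged": "red"},
    "colorblind": {"rroi": "#0072B2", "change": "white", "unchanged": "#D55E00"},
}


def _extent(grid):
    x0, y0 = grid.origin
    return (x0, x0 + grid.n_cols * grid.cell_size, y0, y0 + grid.n_rows * grid.cell_size)


def plot_mppm(mppm: MeanPeakPressureMap, path: str | Path, title: str = "") -> None:
    """Render mean and SD peak-pressure maps side by side."""
    fig, axes = plt.subplots(1, 2, figsize=(7, 6))
    for ax, data, label in ((axes[0], mppm.mean, "mean peak (kPa)"),
                            (axes[1], mppm.sd, "SD (kPa)")):
        im = ax.imshow(data, origin="lower", extent=_extent(mppm.grid), cmap="inferno")
        ax.set_title(label)
        ax.set_xlabel("x (mm)")
        fig.colorbar(im, ax=ax, shrink=0.7)
    axes[0].set_ylabel("y (mm)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rroi_overlay(
    mppm: MeanPeakPressureMap,
    mask: RROIMask,
    path: str | Path,
    palette: str = "clinical",
    title: str = "",
) -> None:
    """Pressure map with R-ROI cells highlighted."""
    colors = _PALETTES[palette]
    fig, ax = plt.subplots(figsize=(4, 7))
    im = ax.imshow(mppm.mean, origin="lower", extent=_extent(mppm.grid), cmap="gray")
    overlay = np.ma.masked_where(~mask.in_rroi, np.ones(mask.in_rroi.shape))
    ax.imshow(
        overlay, origin="lower", extent=_extent(mppm.grid),
        cmap=ListedColormap([colors["rroi"]]), vmin=0, vmax=1, alpha=0.85,
    )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(title or f"R-ROI: {mask.total_area_cm2:.2f} cm$^2$")
    fig.colorbar(im, ax=ax, shrink=0.7, label="mean peak (kPa)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_redistribution(
    mppm: MeanPeakPressureMap,
    mask: RROIMask,
    change: RedistributionMap,
    path: str | Path,
    palette: str = "clinical",
    title: str = "",
) -> None:
    """Overlay of R-ROI, significant changes and unchanged R-ROI cells."""
    colors = _PALETTES[palette]
    fig, ax = plt.subplots(figsize=(4, 7))
    ax.imshow(mppm.mean, origin="lower", extent=_extent(mppm.grid), cmap="gray")
    layers = [
        (mask.in_rroi, colors["rroi"], "R-ROI"),
        (
            (change.category == CATEGORY_SIG_DECREASE)
            | (change.category == CATEGORY_SIG_INCREASE),
            colors["change"],
            "significant change",
        ),
        (change.category == CATEGORY_RROI_UNCHANGED, colors["unchanged"],
         "R-ROI unchanged"),
    ]
    for cells, color, _label in layers:
        if cells.any():
            overlay = np.ma.masked_where(~cells, np.ones(cells.shape))
            ax.imshow(
                overlay, origin="lower", extent=_extent(mppm.grid),
                cmap=ListedColormap([color]), vmin=0, vmax=1, alpha=0.85,
            )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(title or "pressure redistribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_area_boxplot(
    table: AreaTable,
    conditions: list[str],
    path: str | Path,
    title: str = "R-ROI total area by condition",
) -> None:
    """Box plot of per-foot areas with mean (circle), median (square), max (diamond)."""
    data = table.require_complete(conditions)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.boxplot([data[c] for c in conditions], tick_labels=conditions, showfliers=False)
    xs = np.arange(1, len(conditions) + 1)
    ax.scatter(xs, [data[c].mean() for c in conditions], marker="o", zorder=3,
               label="mean")
    ax.scatter(xs, [data[c].median() for c in conditions], marker="s", zorder=3,
               label="median")
    ax.scatter(xs, [data[c].max() for c in conditions], marker="D", zorder=3,
               label="max")
    ax.set_ylabel("total R-ROI area (cm$^2$)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
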