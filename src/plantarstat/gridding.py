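"""Resampling of irregular sensor-layout frames onto a regular grid.

In-shoe sensor matrices use rectangles of unequal sizes; downstream
analysis (peak-pressure maps, risk regions) works on a regular square grid
of 5 mm cells.  Two resampling methods are provided:

``area_weighted`` (default)
    Each cell takes the overlap-area-weighted mean of the sensors covering
    it.  On layouts fully tiled by sensors this conserves total force
    (pressure × area) and is well defined for unequal sensor sizes.
``centroid_bilinear``
    Linear interpolation of sensor-centroid values (clamped to ≥ 0), the
    smoother, non-conservative alternative.

Cells with no sensor coverage receive ``outside_value`` (0 by default) so
that per-cell max/mean statistics stay total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata

from .io import GridFrame, GridSequence, RegularGrid, SensorLayout, SensorRecording

__all__ = ["ResampleConfig", "make_grid_for_layout", "resample_frame", "resample_sequence"]

_METHODS = ("area_weighted", "centroid_bilinear")


@dataclass(frozen=True)
class ResampleConfig:
    method: str = "area_weighted"
    outside_value: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")


def make_grid_for_layout(layout: SensorLayout, cell_size: float = 5.0) -> RegularGrid:
    """Smallest cell-aligned grid covering the union of sensor rectangles.

    The origin is snapped down to a multiple of *cell_size* so grids built
    from overlapping layouts share cell boundaries.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x_min, y_min, x_max, y_max = layout.bounding_box()
    x0 = np.floor(x_min / cell_size) * cell_size
    y0 = np.floor(y_min / cell_size) * cell_size
    n_cols = int(np.ceil((x_max - x0) / cell_size))
    n_rows = int(np.ceil((y_max - y0) / cell_size))
    return RegularGrid(origin=(float(x0), float(y0)), cell_size=cell_size,
                       n_rows=n_rows, n_cols=n_cols)


def _overlap_matrix(layout: SensorLayout, grid: RegularGrid) -> np.ndarray:
    """(n_cells, n_sensors) rectangle-intersection areas in mm²."""
    xe, ye = grid.cell_edges()
    # cell bounds, row-major
    cx0 = np.repeat(ye[:-1], grid.n_cols), np.tile(xe[:-1], grid.n_rows)
    cell_ymin = cx0[0][:, None]
    cell_xmin = cx0[1][:, None]
    cell_ymax = cell_ymin + grid.cell_size
    cell_xmax = cell_xmin + grid.cell_size
    b = layout.bounds  # (n_sensors, 4)
    ix = np.clip(
        np.minimum(cell_xmax, b[None, :, 2]) - np.maximum(cell_xmin, b[None, :, 0]),
        0.0, None,
    )
    iy = np.clip(
        np.minimum(cell_ymax, b[None, :, 3]) - np.maximum(cell_ymin, b[None, :, 1]),
        0.0, None,
    )
    return ix * iy


def resample_frame(
    frame: np.ndarray,
    layout: SensorLayout,
    grid: RegularGrid,
    config: ResampleConfig = ResampleConfig(),
    timestamp: float = 0.0,
) -> GridFrame:
    """Resample one per-sensor pressure vector onto *grid*."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (layout.n_sensors,):
        raise ValueError(
            f"frame length {frame.shape} does not match {layout.n_sensors} sensors"
        )
    if config.method == "area_weighted":
        w = _overlap_matrix(layout, grid)  # (n_cells, n_sensors)
        denom = w.sum(axis=1)
        num = w @ frame
        values = np.full(denom.shape, config.outside_value, dtype=float)
        covered = denom > 0
        values[covered] = num[covered] / denom[covered]
    else:  # centroid_bilinear
        xs, ys = grid.cell_centres()
        gx, gy = np.meshgrid(xs, ys)
        values = griddata(
            layout.centroids, frame, (gx, gy), method="linear",
            fill_value=config.outside_value,
        ).ravel()
        values = np.clip(values, 0.0, None)
    return GridFrame(grid, values.reshape(grid.shape), timestamp)


def resample_sequence(
    rec: SensorRecording,
    grid: RegularGrid | None = None,
    config: ResampleConfig = ResampleConfig(),
    cell_size: float = 5.0,
) -> GridSequence:
    """Resample a whole recording frame-by-frame; timestamps are preserved."""
    if rec.n_frames == 0:
        raise ValueError("empty recording")
    if grid is None:
        grid = make_grid_for_layout(rec.layout, cell_size)
    if config.method == "area_weighted":
        # vectorized over frames: same overlap weights for every frame
        w = _overlap_matrix(rec.layout, grid)
        denom = w.sum(axis=1)
        num = rec.frames @ w.T  # (n_frames, n_cells)
        values = np.full(num.shape, config.outside_value, dtype=float)
        covered = denom > 0
        values[:, covered] = num[:, covered] / denom[covered]
        values = values.reshape(rec.n_frames, grid.n_rows, grid.n_cols)
    else:
        values = np.stack(
            [
                resample_frame(f, rec.layout, grid, config).values
                for f in rec.frames
            ]
        )
    return GridSequence(
        grid=grid,
        values=values,
        timestamps=rec.timestamps,
        sample_rate=rec.sample_rate,
        meta=rec.meta,
    )
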