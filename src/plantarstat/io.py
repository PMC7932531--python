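"""Domain types and readers/writers for in-shoe plantar pressure data.

In-shoe pedobarographic systems record pressure (kPa) on an irregular
matrix of capacitive sensors of unequal sizes, sampled at a fixed rate
(typically 50 Hz) within a bounded measurement range (20–600 kPa for the
devices this package targets).  Two representations are used throughout:

``SensorRecording``
    time-ordered per-sensor pressures over an irregular :class:`SensorLayout`;
``GridSequence``
    the same data resampled onto a regular square grid (5 mm cells by
    default), the representation on which peak-pressure maps and risk
    regions are computed.

Since vendor-native export formats are proprietary, the canonical on-disk
format here is an open, documented CSV dialect ("PressureCSV"); see
:func:`read_sensor_recording`.  Per-foot risk-region area tables (the unit
of group-level analysis) are plain CSV/XLSX read into :class:`AreaTable`.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRESSURE_FLOOR_KPA",
    "PRESSURE_CEIL_KPA",
    "SensorLayout",
    "RecordingMeta",
    "SensorRecording",
    "RegularGrid",
    "GridFrame",
    "GridSequence",
    "AreaTable",
    "FormatError",
    "read_sensor_layout",
    "write_sensor_layout",
    "read_sensor_recording",
    "write_sensor_recording",
    "read_grid_sequence",
    "write_grid_sequence",
    "read_area_table",
    "clip_to_range",
]

logger = logging.getLogger(__name__)

#: Device measurement range: pressures below the floor are unresolvable and
#: treated as 0; pressures above the ceiling saturate.
PRESSURE_FLOOR_KPA = 20.0
PRESSURE_CEIL_KPA = 600.0


class FormatError(ValueError):
    """Raised for malformed pressure-data files; message names the line."""


# ---------------------------------------------------------------------------
# sensor-level types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorLayout:
    """Irregular sensor matrix: axis-aligned rectangles in foot-local mm.

    Coordinates follow the package convention: origin at the
    posterior-lateral heel corner, y increasing toward the toes.  Left feet
    may be mirrored to canonical right-foot orientation by the caller; no
    mirroring is applied implicitly.

    Parameters
    ----------
    sensor_ids : (n,) int array
        Unique sensor identifiers.
    bounds : (n, 4) float array
        Per-sensor ``(x_min, y_min, x_max, y_max)`` in mm.  Rectangles may
        differ in size (sensor dimensions depend on their location on the
        insole).
    side : {"left", "right"}
    """

    sensor_ids: np.ndarray
    bounds: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        ids = np.asarray(self.sensor_ids, dtype=int)
        b = np.asarray(self.bounds, dtype=float)
        if ids.ndim != 1 or ids.size == 0:
            raise ValueError("layout needs at least one sensor")
        if len(np.unique(ids)) != ids.size:
            raise ValueError("sensor_ids must be unique")
        if b.shape != (ids.size, 4):
            raise ValueError("bounds must be (n_sensors, 4)")
        if np.any(b[:, 2] <= b[:, 0]) or np.any(b[:, 3] <= b[:, 1]):
            raise ValueError("sensor rectangles must have positive width and height")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        object.__setattr__(self, "sensor_ids", ids)
        object.__setattr__(self, "bounds", b)

    @property
    def n_sensors(self) -> int:
        return self.sensor_ids.size

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) sensor centre coordinates in mm."""
        b = self.bounds
        return np.column_stack([(b[:, 0] + b[:, 2]) / 2.0, (b[:, 1] + b[:, 3]) / 2.0])

    @property
    def areas_mm2(self) -> np.ndarray:
        b = self.bounds
        return (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])

    def bounding_box(self) -> tuple[float, float, float, float]:
        b = self.bounds
        return (
            float(b[:, 0].min()),
            float(b[:, 1].min()),
            float(b[:, 2].max()),
            float(b[:, 3].max()),
        )


@dataclass(frozen=True)
class RecordingMeta:
    subject: str = ""
    side: str = "right"
    condition: str = ""


@dataclass
class SensorRecording:
    """Time-ordered per-sensor pressures (kPa) for one foot and condition."""

    layout: SensorLayout
    frames: np.ndarray  # (n_frames, n_sensors) kPa
    sample_rate: float = 50.0
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 2 or f.shape[1] != self.layout.n_sensors:
            raise ValueError(
                f"frames must be (n_frames, {self.layout.n_sensors}); got {f.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate


# ---------------------------------------------------------------------------
# grid-level types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegularGrid:
    """Regular square-cell grid in foot-local mm; 5 mm cells by default."""

    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 5.0
    n_rows: int = 0
    n_cols: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def cell_area_cm2(self) -> float:
        """Area of one cell in cm² (0.25 cm² at the default 5 mm)."""
        return (self.cell_size / 10.0) ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinate arrays; row index maps to y, col to x."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def cell_edges(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        xs = x0 + np.arange(self.n_cols + 1) * self.cell_size
        ys = y0 + np.arange(self.n_rows + 1) * self.cell_size
        return xs, ys


@dataclass(frozen=True)
class GridFrame:
    """One resampled pressure frame on a :class:`RegularGrid`."""

    grid: RegularGrid
    values: np.ndarray  # (n_rows, n_cols) kPa
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        if np.any(v < 0):
            raise ValueError("pressures must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass
class GridSequence:
    """Ordered grid frames sharing one grid; the unit of gait analysis."""

    grid: RegularGrid
    values: np.ndarray  # (n_frames, n_rows, n_cols)
    timestamps: np.ndarray
    sample_rate: float = 50.0
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.timestamps, dtype=float)
        if v.ndim != 3 or v.shape[1:] != self.grid.shape:
            raise ValueError(
                f"values must be (n_frames, {self.grid.n_rows}, {self.grid.n_cols})"
            )
        if v.shape[0] == 0:
            raise ValueError("empty sequence")
        if t.shape != (v.shape[0],):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.values = v
        self.timestamps = t

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def frame(self, i: int) -> GridFrame:
        return GridFrame(self.grid, self.values[i], float(self.timestamps[i]))


@dataclass
class AreaTable:
    """Per-foot total R-ROI area (cm²) per condition.

    Wraps a DataFrame indexed by ``(subject, side)`` with one column per
    condition label.  This is the unit of group-level comparison.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.nlevels != 2:
            raise ValueError("AreaTable index must be (subject, side)")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate (subject, side) keys: {dupes}")
        if (df < 0).any().any():
            raise ValueError("areas must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_feet(self) -> int:
        return len(self.data)

    def require_complete(self, conditions: Sequence[str]) -> pd.DataFrame:
        """Return rows restricted to *conditions*, erroring on missing cells."""
        missing = [c for c in conditions if c not in self.data.columns]
        if missing:
            raise ValueError(f"conditions not in table: {missing}")
        sub = self.data[list(conditions)]
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        if bad:
            raise ValueError(f"missing area values for feet: {bad}")
        return sub


# ---------------------------------------------------------------------------
# measurement-range handling
# ---------------------------------------------------------------------------


def clip_to_range(
    values: np.ndarray,
    floor: float = PRESSURE_FLOOR_KPA,
    ceil: float = PRESSURE_CEIL_KPA,
) -> tuple[np.ndarray, int]:
    """Apply the device measurement range to raw pressures.

    Values below *floor* are unresolvable and set to 0 (keeping max/mean
    semantics total); values above *ceil* saturate and are clipped, with the
    number of clipped samples returned.  Idempotent.
    """
    v = np.asarray(values, dtype=float).copy()
    v[v < floor] = 0.0
    n_clipped = int(np.count_nonzero(v > ceil))
    v[v > ceil] = ceil
    return v, n_clipped


# ---------------------------------------------------------------------------
# PressureCSV: sensor layout + recording
# ---------------------------------------------------------------------------

_LAYOUT_COLUMNS = ["sensor_id", "x_min_mm", "y_min_mm", "x_max_mm", "y_max_mm"]


def read_sensor_layout(path: str | Path, side: str = "right") -> SensorLayout:
    """Read a layout CSV with columns ``sensor_id,x_min_mm,y_min_mm,x_max_mm,y_max_mm``."""
    df = pd.read_csv(path)
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: layout file missing columns {missing}")
    return SensorLayout(
        sensor_ids=df["sensor_id"].to_numpy(int),
        bounds=df[_LAYOUT_COLUMNS[1:]].to_numpy(float),
        side=side,
    )


def write_sensor_layout(layout: SensorLayout, path: str | Path) -> None:
    df = pd.DataFrame(layout.bounds, columns=_LAYOUT_COLUMNS[1:])
    df.insert(0, "sensor_id", layout.sensor_ids)
    df.to_csv(path, index=False)


def _parse_header_comments(lines: list[str], path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" not in body:
            raise FormatError(f"{path}:{lineno}: malformed header line {line!r}")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def read_sensor_recording(
    path: str | Path,
    layout: SensorLayout | None = None,
) -> SensorRecording:
    """Read a PressureCSV recording.

    Format::

        # layout=<layout file, relative to this file>
        # sample_rate_hz=50
        # side=left|right
        # subject=<id>            (optional)
        # condition=<label>       (optional)
        t_s,s001,s002,...
        0.00,123.4,...

    The explicit *layout* argument overrides the ``layout=`` header.  On
    read, the device measurement range is applied: values below 20 kPa are
    stored as 0; values above 600 kPa are clipped to 600 and the number of
    clipped samples is logged.

    Raises
    ------
    FormatError
        On a malformed header, a frame whose width does not match the
        sensor count, or a non-numeric value — naming the line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _parse_header_comments(lines, path)
    n_header = sum(1 for line in lines if line.startswith("#"))

    if layout is None:
        if "layout" not in meta:
            raise FormatError(f"{path}: no layout given and no '# layout=' header")
        layout = read_sensor_layout(
            path.parent / meta["layout"], side=meta.get("side", "right")
        )

    body = lines[n_header:]
    if not body:
        raise FormatError(f"{path}: no column header row")
    columns = [c.strip() for c in body[0].split(",")]
    if columns[0] != "t_s" or len(columns) - 1 != layout.n_sensors:
        raise FormatError(
            f"{path}:{n_header + 1}: expected 't_s' plus {layout.n_sensors} "
            f"sensor columns, got {len(columns) - 1}"
        )

    rows = []
    for offset, line in enumerate(body[1:], start=n_header + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != len(columns):
            raise FormatError(
                f"{path}:{offset}: frame has {len(parts) - 1} values, "
                f"expected {layout.n_sensors}"
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise FormatError(f"{path}:{offset}: non-numeric value ({exc})") from None

    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise FormatError(f"{path}: recording contains no frames")
    values, n_clipped = clip_to_range(arr[:, 1:])
    if n_clipped:
        logger.info("%s: clipped %d samples above %g kPa", path, n_clipped, PRESSURE_CEIL_KPA)

    return SensorRecording(
        layout=layout,
        frames=values,
        sample_rate=float(meta.get("sample_rate_hz", 50.0)),
        meta=RecordingMeta(
            subject=meta.get("subject", ""),
            side=meta.get("side", layout.side),
            condition=meta.get("condition", ""),
        ),
    )


def write_sensor_recording(
    rec: SensorRecording,
    path: str | Path,
    layout_filename: str | None = None,
) -> None:
    """Write a PressureCSV recording (and its layout file alongside)."""
    path = Path(path)
    if layout_filename is None:
        layout_filename = path.stem + "_layout.csv"
    write_sensor_layout(rec.layout, path.parent / layout_filename)

    buf = _io.StringIO()
    buf.write(f"# layout={layout_filename}\n")
    buf.write(f"# sample_rate_hz={rec.sample_rate:g}\n")
    buf.write(f"# side={rec.meta.side}\n")
    if rec.meta.subject:
        buf.write(f"# subject={rec.meta.subject}\n")
    if rec.meta.condition:
        buf.write(f"# condition={rec.meta.condition}\n")
    cols = ["t_s"] + [f"s{sid:03d}" for sid in rec.layout.sensor_ids]
    buf.write(",".join(cols) + "\n")
    for t, frame in zip(rec.timestamps, rec.frames):
        buf.write(",".join([f"{t:.6g}"] + [f"{v:.10g}" for v in frame]) + "\n")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# GridSequence CSV
# ---------------------------------------------------------------------------


def write_grid_sequence(seq: GridSequence, path: str | Path) -> None:
    """Write a grid sequence as CSV.

    Header comments carry the grid geometry and metadata; each data row is
    one frame: timestamp followed by row-major cell values.  Round-trips
    bit-for-bit on values (full float precision is written).
    """
    path = Path(path)
    g = seq.grid
    buf = _io.StringIO()
    buf.write(
        f"# grid={g.origin[0]:.17g},{g.origin[1]:.17g},{g.cell_size:.17g},"
        f"{g.n_rows},{g.n_cols}\n"
    )
    buf.write(f"# sample_rate_hz={seq.sample_rate:.17g}\n")
    buf.write(f"# side={seq.meta.side}\n")
    if seq.meta.subject:
        buf.write(f"# subject={seq.meta.subject}\n")
    if seq.meta.condition:
        buf.write(f"# condition={seq.meta.condition}\n")
    ncell = g.n_rows * g.n_cols
    buf.write(",".join(["t_s"] + [f"c{i}" for i in range(ncell)]) + "\n")
    for t, frame in zip(seq.timestamps, seq.values):
        row = [np.format_float_positional(t, unique=True)] + [
            np.format_float_positional(v, unique=True) for v in frame.ravel()
        ]
        buf.write(",".join(row) + "\n")
    path.write_text(buf.getvalue())


def read_grid_sequence(path: str | Path) -> GridSequence:
    """Read a grid sequence written by :func:`write_grid_sequence`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = _parse_header_comments(lines, path)
    if "grid" not in meta:
        raise FormatError(f"{path}: missing '# grid=' header")
    parts = meta["grid"].split(",")
    if len(parts) != 5:
        raise FormatError(f"{path}: malformed grid header {meta['grid']!r}")
    x0, y0, cell = (float(p) for p in parts[:3])
    n_rows, n_cols = int(parts[3]), int(parts[4])
    grid = RegularGrid((x0, y0), cell, n_rows, n_cols)

    n_header = sum(1 for line in lines if line.startswith("#"))
    body = [line for line in lines[n_header + 1 :] if line.strip()]
    if not body:
        raise FormatError(f"{path}: empty sequence")
    ncell = n_rows * n_cols
    ts, frames = [], []
    for offset, line in enumerate(body, start=n_header + 2):
        parts = line.split(",")
        if len(parts) != ncell + 1:
            raise FormatError(
                f"{path}:{offset}: frame has {len(parts) - 1} cells, expected {ncell}"
            )
        try:
            ts.append(float(parts[0]))
            frames.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{offset}: non-numeric value ({exc})") from None

    values = np.asarray(frames, dtype=float).reshape(len(frames), n_rows, n_cols)
    return GridSequence(
        grid=grid,
        values=values,
        timestamps=np.asarray(ts),
        sample_rate=float(meta.get("sample_rate_hz", 50.0)),
        meta=RecordingMeta(
            subject=meta.get("subject", ""),
            side=meta.get("side", "right"),
            condition=meta.get("condition", ""),
        ),
    )


# ---------------------------------------------------------------------------
# Area tables
# ---------------------------------------------------------------------------


def read_area_table(path: str | Path) -> AreaTable:
    """Read a per-foot R-ROI area table (CSV or XLSX).

    Expected columns: ``subject, side, <condition>, ...`` with areas in cm².
    Duplicate (subject, side) rows and negative areas are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    for col in ("subject", "side"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.set_index(["subject", "side"])
    df = df.apply(pd.to_numeric)
    return AreaTable(df)


def write_area_table(table: AreaTable, path: str | Path) -> None:
    table.data.reset_index().to_csv(path, index=False)


def mirror_layout(layout: SensorLayout) -> SensorLayout:
    """Mirror a left-foot layout about its x extent to right-foot orientation."""
    x_min, _, x_max, _ = layout.bounding_box()
    b = layout.bounds.copy()
    new_xmin = x_min + x_max - b[:, 2]
    new_xmax = x_min + x_max - b[:, 0]
    b[:, 0], b[:, 2] = new_xmin, new_xmax
    side = "right" if layout.side == "left" else "left"
    return replace(layout, bounds=b, side=side)
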