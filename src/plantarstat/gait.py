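"""Stance-phase segmentation and peak-pressure map statistics.

Gait is a cyclic alternation of stance (foot on ground) and swing phases;
successive stances differ slightly in duration and loading, so per-cell
statistics must be taken over many steps.  The pipeline is:

1. segment the grid sequence into stance phases (:func:`detect_stances`);
2. per stance, take the per-cell maximum over its frames — the
   peak-pressure map (:func:`peak_pressure_map`);
3. average the peak maps cell-wise into the mean peak pressure map (MPPM)
   with its per-cell sample SD (:func:`mean_peak_map`).

A contact frame is one where at least ``min_contact_cells`` cells read at
or above the ``contact_pressure_floor`` (20 kPa, the device floor); contact
runs of physiological duration become stances, and the first/last steps of
each walking pass are trimmed as gait-initiation/termination artefacts.

The default ``min_n`` of 24 steps comes from an a priori power analysis
(see :mod:`plantarstat.power`): 24 paired steps detect a standardized
difference d = 0.6 at 80% power, α = 0.05, two-tailed.  Fewer steps produce
a warning, not an error — the requirement is a power property, not a
validity condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GridSequence, RegularGrid

__all__ = [
    "StanceConfig",
    "StancePhase",
    "PeakPressureMap",
    "MeanPeakPressureMap",
    "UnderpoweredWarning",
    "detect_stances",
    "peak_pressure_map",
    "peak_maps_for_stances",
    "mean_peak_map",
]


class UnderpoweredWarning(UserWarning):
    """Fewer steps collected than the a priori power analysis requires."""


@dataclass(frozen=True)
class StanceConfig:
    contact_pressure_floor: float = 20.0  # kPa, device floor
    min_contact_cells: int = 4
    min_stance_frames: int = 10  # 0.2 s at 50 Hz
    max_stance_frames: int = 120  # 2.4 s at 50 Hz
    trim_steps_per_pass: int = 1

    def __post_init__(self) -> None:
        if min(self.contact_pressure_floor, self.min_contact_cells,
               self.min_stance_frames, self.max_stance_frames) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.trim_steps_per_pass < 0:
            raise ValueError("trim_steps_per_pass must be >= 0")
        if self.min_stance_frames >= self.max_stance_frames:
            raise ValueError("min_stance_frames must be < max_stance_frames")


@dataclass(frozen=True)
class StancePhase:
    """Half-open frame interval [start_frame, end_frame) of one stance."""

    start_frame: int
    end_frame: int
    step_index: int

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("stance must span at least one frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class PeakPressureMap:
    """Per-cell maximum pressure (kPa) over one stance phase."""

    grid: RegularGrid
    values: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(v < 0):
            raise ValueError("pressures must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MeanPeakPressureMap:
    """Cell-wise mean and sample SD (ddof=1) of peak maps over n stances."""

    grid: RegularGrid
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if m.shape != self.grid.shape or s.shape != self.grid.shape:
            raise ValueError("mean/sd shape does not match grid")
        if np.any(s < 0):
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("MPPM needs at least 2 stances for a sample SD")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)


def _contact_runs(contact: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    padded = np.concatenate([[False], contact, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_stances(
    seq: GridSequence,
    cfg: StanceConfig = StanceConfig(),
    pass_boundaries: Sequence[int] | None = None,
) -> list[StancePhase]:
    """Segment a grid sequence into stance phases.

    A frame is in contact iff at least ``cfg.min_contact_cells`` cells are
    at or above ``cfg.contact_pressure_floor``.  Maximal contact runs whose
    duration lies within ``[min_stance_frames, max_stance_frames]`` become
    stances; within each walking pass the first and last
    ``trim_steps_per_pass`` stances are dropped.  A pass is the whole
    recording unless *pass_boundaries* (frame indices splitting the
    recording) are supplied.

    Returns a possibly empty list; never raises on quiet input.
    """
    contact = (
        (seq.values >= cfg.contact_pressure_floor).sum(axis=(1, 2))
        >= cfg.min_contact_cells
    )
    bounds = [0, *sorted(pass_boundaries or []), seq.n_frames]
    phases: list[StancePhase] = []
    step = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        runs = [
            (s + lo, e + lo)
            for s, e in _contact_runs(contact[lo:hi])
            if cfg.min_stance_frames <= e - s <= cfg.max_stance_frames
        ]
        t = cfg.trim_steps_per_pass
        if t:
            runs = runs[t:-t] if len(runs) > 2 * t else []
        for s, e in runs:
            phases.append(StancePhase(s, e, step))
            step += 1
    return phases


def peak_pressure_map(seq: GridSequence, phase: StancePhase) -> PeakPressureMap:
    """Per-cell maximum over the frames of one stance phase."""
    if phase.start_frame < 0 or phase.end_frame > seq.n_frames:
        raise ValueError(
            f"stance [{phase.start_frame}, {phase.end_frame}) outside "
            f"sequence of {seq.n_frames} frames"
        )
    values = seq.values[phase.start_frame : phase.end_frame].max(axis=0)
    return PeakPressureMap(seq.grid, values, phase.step_index)


def peak_maps_for_stances(
    seq: GridSequence, phases: Sequence[StancePhase]
) -> list[PeakPressureMap]:
    return [peak_pressure_map(seq, p) for p in phases]


def mean_peak_map(
    maps: Sequence[PeakPressureMap], min_n: int = 24
) -> MeanPeakPressureMap:
    """Cell-wise mean and sample SD of peak-pressure maps.

    Warns (:class:`UnderpoweredWarning`) when fewer than *min_n* maps are
    supplied; 24 is the step count required for 80% power at d = 0.6 in the
    paired per-cell comparison the framework performs downstream.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 peak maps for mean and SD")
    grid = maps[0].grid
    if any(m.grid != grid for m in maps[1:]):
        raise ValueError("peak maps are on different grids")
    if len(maps) < min_n:
        warnings.warn(
            f"only {len(maps)} stances collected; the a priori power analysis "
            f"requires at least {min_n} steps for 80% power at d = 0.6",
            UnderpoweredWarning,
            stacklevel=2,
        )
    stack = np.stack([m.values for m in maps])
    return MeanPeakPressureMap(
        grid=grid,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        n=len(maps),
    )
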