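"""Synthetic in-shoe gait pressure generator with known ground truth.

Emulates the data a pedobarographic insole system produces during walking:
cyclic stance/swing alternation at 50 Hz, a foot-shaped pressure field
with discrete high-pressure loci (heel, metatarsal heads, hallux — the
clinically typical callosity sites), step-to-step variability in loading
amplitude, locus position and stance duration, sensor noise, and the
20–600 kPa measurement range of the device.  Insole-induced offloading is
emulated by scaling down locus amplitudes and optionally rerouting part of
the removed load to a midfoot/arch locus (:func:`apply_offload`) — the
net effect of a pressure-deepening custom insole, without modelling the
insole itself.

Within a stance, loading rolls from heel to forefoot: the baseline
(whole-sole contact) field follows a half-sine over the stance, and each
locus follows a half-sine within its own timing window, so the per-cell
maximum over the stance realizes the template's peak field.  Ground-truth
helpers (:func:`expected_peak_map`, :func:`ground_truth_rroi`,
:func:`detectable_change_masks`) expose what the downstream pipeline
should recover, enabling end-to-end parameter-recovery tests.

What this generator does *not* emulate: shear stress, centre-of-pressure
dynamics, foot deformity geometry, or material mechanics of real insoles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .gridding import _overlap_matrix
from .io import (
    GridSequence,
    RecordingMeta,
    RegularGrid,
    SensorLayout,
    SensorRecording,
    clip_to_range,
)
from .rroi import RROIConfig, RROIMask, _label_clusters

__all__ = [
    "Locus",
    "FootTemplate",
    "VariabilityModel",
    "OffloadSpec",
    "default_foot_template",
    "simulate_walk",
    "apply_offload",
    "expected_peak_map",
    "ground_truth_rroi",
    "detectable_change_masks",
    "synthetic_pedar_layout",
    "sensor_recording_from_sequence",
]


@dataclass(frozen=True)
class Locus:
    """One discrete high-pressure site: an isotropic Gaussian bump."""

    center: tuple[float, float]  # (x, y) mm
    sd_mm: float
    amplitude_kpa: float
    window: tuple[float, float] = (0.0, 1.0)  # active fraction of stance
    role: str = ""  # e.g. "heel", "met1", "hallux", "arch"

    def __post_init__(self) -> None:
        if self.amplitude_kpa < 0:
            raise ValueError("amplitude must be non-negative")
        if self.sd_mm <= 0:
            raise ValueError("sd_mm must be positive")
        t0, t1 = self.window
        if not 0.0 <= t0 < t1 <= 1.0:
            raise ValueError("window must satisfy 0 <= t0 < t1 <= 1")


@dataclass(frozen=True)
class FootTemplate:
    """Foot outline plus pressure loci defining the expected peak field."""

    grid: RegularGrid
    mask: np.ndarray  # bool (n_rows, n_cols), foot outline
    loci: tuple[Locus, ...]
    baseline_kpa: float = 60.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.baseline_kpa < 0:
            raise ValueError("baseline must be non-negative")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "loci", tuple(self.loci))
        xs, ys = self.grid.cell_centres()
        for locus in self.loci:
            cx, cy = locus.center
            col = int(np.clip(np.argmin(np.abs(xs - cx)), 0, self.grid.n_cols - 1))
            row = int(np.clip(np.argmin(np.abs(ys - cy)), 0, self.grid.n_rows - 1))
            if not m[row, col]:
                raise ValueError(f"locus {locus.role or locus.center} outside foot mask")


@dataclass(frozen=True)
class VariabilityModel:
    """Step-to-step and sensor-level variability of the simulated gait.

    amplitude_cv : multiplicative coefficient of variation of the per-step
        loading factor (one factor per step, applied to the whole field).
    jitter_sd_mm : SD of the per-step random displacement of each locus.
    stance_duration_mean_s, stance_duration_sd_s : stance time distribution
        (0.7 ± 0.05 s — physiological comfortable walking).
    sensor_noise_sd_kpa : additive white measurement noise per frame.
    seed : RNG seed; identical seeds reproduce identical sequences.
    """

    amplitude_cv: float = 0.1
    jitter_sd_mm: float = 2.0
    stance_duration_mean_s: float = 0.7
    stance_duration_sd_s: float = 0.05
    sensor_noise_sd_kpa: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("amplitude_cv", "jitter_sd_mm", "stance_duration_sd_s",
                     "sensor_noise_sd_kpa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.stance_duration_mean_s <= 0:
            raise ValueError("stance_duration_mean_s must be positive")

    @property
    def noiseless(self) -> bool:
        return (
            self.amplitude_cv == 0
            and self.jitter_sd_mm == 0
            and self.stance_duration_sd_s == 0
            and self.sensor_noise_sd_kpa == 0
        )


@dataclass(frozen=True)
class OffloadSpec:
    """Emulated offloading effect of a custom insole.

    reduction : fraction in [0, 1] by which each locus amplitude is scaled
        down — a scalar applied to every super-threshold locus, or one
        fraction per locus.
    redistribution_fraction : share of the removed peak load rerouted to
        the arch locus (created at the midfoot if the template has none),
        emulating arch-profile load transfer.
    threshold_kpa : loci at/above this amplitude count as super-threshold
        when a scalar reduction is given.
    """

    reduction: float | Sequence[float] = 0.0
    redistribution_fraction: float = 0.0
    threshold_kpa: float = 200.0

    def __post_init__(self) -> None:
        reds = np.atleast_1d(np.asarray(self.reduction, dtype=float))
        if np.any((reds < 0) | (reds > 1)):
            raise ValueError("reduction fractions must be in [0, 1]")
        if not 0 <= self.redistribution_fraction <= 1:
            raise ValueError("redistribution_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# default template
# ---------------------------------------------------------------------------


def _ellipse_mask(grid: RegularGrid, cx, cy, rx, ry) -> np.ndarray:
    xs, ys = grid.cell_centres()
    gx, gy = np.meshgrid(xs, ys)
    return ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 <= 1.0


def default_foot_template(cell_size: float = 5.0) -> FootTemplate:
    """Right-foot template, ~100 × 260 mm, with clinically typical loci.

    Heel, five metatarsal heads and hallux carry discrete high-pressure
    bumps; a low-amplitude arch locus sits at the midfoot.  Amplitudes are
    set so that, with the default 60 kPa whole-sole baseline, the
    super-threshold (≥ 200 kPa) area under a flat insole is in the range
    reported for at-risk neuropathic feet (~20 cm² per foot).
    """
    n_cols = int(round(100.0 / cell_size))
    n_rows = int(round(260.0 / cell_size))
    grid = RegularGrid((0.0, 0.0), cell_size, n_rows, n_cols)
    mask = (
        _ellipse_mask(grid, 50, 45, 34, 42)       # heel
        | _ellipse_mask(grid, 55, 120, 30, 55)    # midfoot (lateral-shifted)
        | _ellipse_mask(grid, 50, 195, 46, 58)    # forefoot + toes
    )
    loci = (
        Locus((50, 40), 14.0, 260.0, (0.05, 0.45), "heel"),
        Locus((72, 185), 10.0, 280.0, (0.40, 0.85), "met1"),
        Locus((58, 192), 9.0, 250.0, (0.40, 0.85), "met2"),
        Locus((44, 192), 9.0, 220.0, (0.40, 0.85), "met3"),
        Locus((31, 188), 8.0, 180.0, (0.40, 0.85), "met4"),
        Locus((19, 180), 8.0, 150.0, (0.40, 0.85), "met5"),
        Locus((68, 235), 8.0, 260.0, (0.55, 0.95), "hallux"),
        Locus((62, 115), 12.0, 40.0, (0.30, 0.70), "arch"),
    )
    return FootTemplate(grid, mask, loci, baseline_kpa=60.0)


# ---------------------------------------------------------------------------
# field assembly
# ---------------------------------------------------------------------------


def _locus_fields(
    template: FootTemplate, centers: np.ndarray | None = None
) -> np.ndarray:
    """(n_loci, n_rows, n_cols) spatial bump fields, masked to the foot."""
    xs, ys = template.grid.cell_centres()
    gx, gy = np.meshgrid(xs, ys)
    if centers is None:
        centers = np.asarray([l.center for l in template.loci])
    fields = np.empty((len(template.loci), *template.grid.shape))
    for i, locus in enumerate(template.loci):
        cx, cy = centers[i]
        r2 = (gx - cx) ** 2 + (gy - cy) ** 2
        fields[i] = locus.amplitude_kpa * np.exp(-r2 / (2.0 * locus.sd_mm**2))
    return fields * template.mask


def _temporal_weights(template: FootTemplate, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and per-locus half-sine activation over one stance."""
    tau = (np.arange(n_frames) + 0.5) / n_frames
    w0 = np.sin(np.pi * tau)
    wl = np.zeros((len(template.loci), n_frames))
    for i, locus in enumerate(template.loci):
        t0, t1 = locus.window
        inside = (tau >= t0) & (tau <= t1)
        wl[i, inside] = np.sin(np.pi * (tau[inside] - t0) / (t1 - t0))
    return w0, wl


def _stance_frames(
    template: FootTemplate,
    n_frames: int,
    fields: np.ndarray,
    base_field: np.ndarray,
) -> np.ndarray:
    w0, wl = _temporal_weights(template, n_frames)
    # (T, R, C) = baseline roll-through + locus activations
    return w0[:, None, None] * base_field[None] + np.tensordot(
        wl.T, fields, axes=(1, 0)
    )


def simulate_walk(
    template: FootTemplate,
    var: VariabilityModel = VariabilityModel(),
    n_steps: int = 30,
    sample_rate: float = 50.0,
    swing_duration_s: float = 0.4,
    meta: RecordingMeta | None = None,
) -> GridSequence:
    """Simulate a walking recording as a grid sequence.

    Alternates stance and swing phases; each stance applies one global
    amplitude factor (1 + cv·z), per-locus positional jitter, additive
    sensor noise, and finally the 20–600 kPa measurement range (sub-floor
    values zeroed, saturation clipped).  Fully reproducible from
    ``var.seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(var.seed)
    base_field = template.baseline_kpa * template.mask.astype(float)
    static_fields = _locus_fields(template)
    centers0 = np.asarray([l.center for l in template.loci])
    swing = int(round(swing_duration_s * sample_rate))
    swing_block = np.zeros((max(swing, 1), *template.grid.shape))

    blocks = [swing_block]
    for _ in range(n_steps):
        dur = var.stance_duration_mean_s
        if var.stance_duration_sd_s > 0:
            dur += var.stance_duration_sd_s * rng.standard_normal()
        dur = float(np.clip(dur, 0.3, 1.5))
        n_frames = max(int(round(dur * sample_rate)), 5)

        if var.jitter_sd_mm > 0:
            centers = centers0 + rng.normal(0, var.jitter_sd_mm, centers0.shape)
            fields = _locus_fields(template, centers)
        else:
            fields = static_fields
        factor = 1.0
        if var.amplitude_cv > 0:
            factor = max(1.0 + var.amplitude_cv * rng.standard_normal(), 0.05)
        frames = factor * _stance_frames(template, n_frames, fields, base_field)
        if var.sensor_noise_sd_kpa > 0:
            frames = frames + rng.normal(0, var.sensor_noise_sd_kpa, frames.shape)
        blocks.append(frames)
        blocks.append(swing_block)

    values = np.concatenate(blocks, axis=0)
    values, _ = clip_to_range(values)
    return GridSequence(
        grid=template.grid,
        values=values,
        timestamps=np.arange(values.shape[0]) / sample_rate,
        sample_rate=sample_rate,
        meta=meta or RecordingMeta(condition="simulated"),
    )


# ---------------------------------------------------------------------------
# offloading and ground truth
# ---------------------------------------------------------------------------


def apply_offload(template: FootTemplate, spec: OffloadSpec) -> FootTemplate:
    """Emulate a custom insole's offloading on a template.

    Locus amplitudes are scaled by (1 − reduction); the removed peak load,
    weighted by ``redistribution_fraction``, is added to the arch locus
    (created at the midfoot if absent).
    """
    loci = list(template.loci)
    reds = np.asarray(spec.reduction, dtype=float)
    if reds.ndim == 0:
        reds = np.array([
            float(reds) if l.amplitude_kpa >= spec.threshold_kpa and l.role != "arch"
            else 0.0
            for l in loci
        ])
    elif reds.shape != (len(loci),):
        raise ValueError(f"need one reduction per locus ({len(loci)}), got {reds.shape}")

    removed = 0.0
    new_loci = []
    for locus, r in zip(loci, reds):
        removed += locus.amplitude_kpa * r
        new_loci.append(replace(locus, amplitude_kpa=locus.amplitude_kpa * (1.0 - r)))

    if spec.redistribution_fraction > 0 and removed > 0:
        arch_idx = next((i for i, l in enumerate(new_loci) if l.role == "arch"), None)
        added = spec.redistribution_fraction * removed
        if arch_idx is None:
            x0, y0 = template.grid.origin
            cx = x0 + template.grid.n_cols * template.grid.cell_size * 0.55
            cy = y0 + template.grid.n_rows * template.grid.cell_size * 0.45
            new_loci.append(Locus((cx, cy), 12.0, added, (0.3, 0.7), "arch"))
        else:
            arch = new_loci[arch_idx]
            new_loci[arch_idx] = replace(
                arch, amplitude_kpa=arch.amplitude_kpa + added
            )
    return replace(template, loci=tuple(new_loci))


def expected_peak_map(
    template: FootTemplate, sample_rate: float = 50.0, stance_duration_s: float = 0.7
) -> np.ndarray:
    """Noiseless per-cell peak field of one stance (the asymptotic MPPM)."""
    n_frames = max(int(round(stance_duration_s * sample_rate)), 5)
    base_field = template.baseline_kpa * template.mask.astype(float)
    frames = _stance_frames(template, n_frames, _locus_fields(template), base_field)
    peaks, _ = clip_to_range(frames.max(axis=0))
    return peaks


def _jitter_smoothed(template: FootTemplate, jitter_sd_mm: float) -> FootTemplate:
    """Template whose loci are the expectation under positional jitter.

    A Gaussian bump whose centre is displaced by N(0, j²) in each axis has
    expectation equal to a wider, lower bump: σ² → σ² + j², amplitude
    scaled by σ² / (σ² + j²).
    """
    if jitter_sd_mm == 0:
        return template
    loci = tuple(
        replace(
            l,
            sd_mm=math.sqrt(l.sd_mm**2 + jitter_sd_mm**2),
            amplitude_kpa=l.amplitude_kpa * l.sd_mm**2 / (l.sd_mm**2 + jitter_sd_mm**2),
        )
        for l in template.loci
    )
    return replace(template, loci=loci)


def ground_truth_rroi(
    template: FootTemplate,
    var: VariabilityModel = VariabilityModel(),
    cfg: RROIConfig = RROIConfig(),
    sample_rate: float = 50.0,
) -> RROIMask:
    """Asymptotic (infinite-steps) risk region implied by the template.

    As the number of steps grows the standard error vanishes, so every
    statistical inclusion rule converges to the direct comparison of the
    expected peak against the threshold.  The expected peak accounts for
    locus jitter (see :func:`_jitter_smoothed`); the dispersion-band rule
    keeps its SD band, evaluated with the asymptotic per-cell SD
    (amplitude_cv × expected peak) and the normal critical value.
    """
    expected = expected_peak_map(
        _jitter_smoothed(template, var.jitter_sd_mm),
        sample_rate,
        var.stance_duration_mean_s,
    )
    if cfg.rule == "dispersion_band":
        z = stats.norm.ppf(1.0 - cfg.alpha)
        sd = var.amplitude_cv * expected
        in_rroi = (expected >= cfg.threshold) | (
            (cfg.threshold - expected) <= z * sd
        )
    else:
        in_rroi = expected >= cfg.threshold
    labels, n = _label_clusters(in_rroi, cfg.connectivity)
    area = float(np.count_nonzero(in_rroi)) * template.grid.cell_area_cm2
    return RROIMask(template.grid, in_rroi, labels, n, area)


def detectable_change_masks(
    template_ref: FootTemplate,
    template_alt: FootTemplate,
    var: VariabilityModel,
    n_steps: int,
    cfg: RROIConfig = RROIConfig(),
    sample_rate: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (decrease, increase) masks for the redistribution test.

    A cell counts as a true change where the expected paired difference
    exceeds the minimal detectable difference at 50% power,
    Δ* = t_crit · sd_diff / √n — the boundary at which the paired t test's
    detection probability crosses one half.  sd_diff is the asymptotic SD
    of the per-step difference under independent per-step amplitude
    factors: cv · √(P_ref² + P_alt²).
    """
    p_ref = expected_peak_map(
        _jitter_smoothed(template_ref, var.jitter_sd_mm),
        sample_rate, var.stance_duration_mean_s,
    )
    p_alt = expected_peak_map(
        _jitter_smoothed(template_alt, var.jitter_sd_mm),
        sample_rate, var.stance_duration_mean_s,
    )
    diff = p_alt - p_ref
    sd_diff = var.amplitude_cv * np.sqrt(p_ref**2 + p_alt**2)
    sd_diff = np.maximum(sd_diff, var.sensor_noise_sd_kpa * math.sqrt(2) + 1e-9)
    tcrit = stats.t.ppf(1.0 - cfg.alpha / 2.0, n_steps - 1)
    mdd = tcrit * sd_diff / math.sqrt(n_steps)
    return diff < -mdd, diff > mdd


# ---------------------------------------------------------------------------
# synthetic irregular sensor layout
# ---------------------------------------------------------------------------


def synthetic_pedar_layout(side: str = "right") -> SensorLayout:
    """99-sensor irregular layout tiling a 90 × 260 mm insole.

    9 columns × 11 rows of rectangles; row heights vary with longitudinal
    position (larger under heel and forefoot), mirroring the way real
    insole matrices size sensors by location.  Fully tiles its bounding
    box, so area-weighted resampling conserves force exactly.
    """
    heights = [20, 22, 24, 26, 28, 26, 24, 22, 24, 22, 22]  # sums to 260
    width = 10.0
    ids, bounds = [], []
    y = 0.0
    sid = 1
    for h in heights:
        for c in range(9):
            ids.append(sid)
            bounds.append((c * width, y, (c + 1) * width, y + h))
            sid += 1
        y += h
    return SensorLayout(np.array(ids), np.array(bounds, dtype=float), side=side)


def sensor_recording_from_sequence(
    seq: GridSequence, layout: SensorLayout
) -> SensorRecording:
    """Sample a grid sequence onto an irregular sensor layout.

    Each sensor reads the overlap-area-weighted mean of the grid cells it
    covers, then the measurement range is applied — emulating what the
    physical sensor matrix would record of the simulated pressure field.
    """
    w = _overlap_matrix(layout, seq.grid)  # (n_cells, n_sensors)
    denom = w.sum(axis=0)
    if np.any(denom == 0):
        raise ValueError("some sensors lie entirely outside the grid")
    flat = seq.values.reshape(seq.n_frames, -1)
    frames = (flat @ w) / denom
    frames, _ = clip_to_range(frames)
    return SensorRecording(
        layout=layout, frames=frames, sample_rate=seq.sample_rate, meta=seq.meta
    )
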