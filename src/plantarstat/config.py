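"""Run configuration: nested YAML keys mapped onto the analysis dataclasses.

A run config is a YAML mapping with the sections below; unknown keys are
rejected so typos fail loudly, and every command logs the fully resolved
configuration (plus package version) next to its outputs for auditability.

Sections and keys::

    stance:   contact_pressure_floor, min_contact_cells, min_stance_frames,
              max_stance_frames, trim_steps_per_pass
    resample: method, cell_mm
    rroi:     threshold, alpha, rule, connectivity, bonferroni_cells, pairing
    stats:    alpha_family
    power:    family, tails, alpha, power, d, f, k_measurements, corr_rho,
              epsilon_nonsphericity
    sim:      n_steps, sample_rate, amplitude_cv, jitter_sd_mm,
              stance_duration_mean_s, stance_duration_sd_s,
              sensor_noise_sd_kpa, baseline_kpa, offload_reduction,
              offload_redistribution
    seed:     integer
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from .gait import StanceConfig
from .gridding import ResampleConfig
from .power import PowerSpec
from .rroi import RROIConfig

__all__ = ["RunConfig", "load_config", "write_run_log"]

_SIM_KEYS = {
    "n_steps", "sample_rate", "amplitude_cv", "jitter_sd_mm",
    "stance_duration_mean_s", "stance_duration_sd_s", "sensor_noise_sd_kpa",
    "baseline_kpa", "offload_reduction", "offload_redistribution",
}
_STATS_KEYS = {"alpha_family"}


@dataclass
class RunConfig:
    stance: StanceConfig = field(default_factory=StanceConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    cell_mm: float = 5.0
    rroi: RROIConfig = field(default_factory=RROIConfig)
    alpha_family: float = 0.05
    power: PowerSpec = field(default_factory=PowerSpec)
    sim: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def resolved(self) -> dict[str, Any]:
        """Fully resolved nested dict of every parameter in effect."""
        return {
            "stance": dataclasses.asdict(self.stance),
            "resample": {**dataclasses.asdict(self.resample), "cell_mm": self.cell_mm},
            "rroi": dataclasses.asdict(self.rroi),
            "stats": {"alpha_family": self.alpha_family},
            "power": dataclasses.asdict(self.power),
            "sim": dict(self.sim),
            "seed": self.seed,
        }


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config, rejecting unknown sections and keys."""
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            raw = loaded
    if overrides:
        raw = {**raw, **overrides}

    known_sections = {"stance", "resample", "rroi", "stats", "power", "sim", "seed"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    cfg = RunConfig()
    if "stance" in raw:
        cfg.stance = _build_section(StanceConfig, raw["stance"], "stance")
    if "resample" in raw:
        rs = dict(raw["resample"])
        cfg.cell_mm = float(rs.pop("cell_mm", 5.0))
        cfg.resample = _build_section(ResampleConfig, rs, "resample")
    if "rroi" in raw:
        cfg.rroi = _build_section(RROIConfig, raw["rroi"], "rroi")
    if "stats" in raw:
        unknown = set(raw["stats"]) - _STATS_KEYS
        if unknown:
            raise ValueError(f"unknown keys in 'stats': {sorted(unknown)}")
        cfg.alpha_family = float(raw["stats"].get("alpha_family", 0.05))
    if "power" in raw:
        cfg.power = _build_section(PowerSpec, raw["power"], "power")
    if "sim" in raw:
        unknown = set(raw["sim"]) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown keys in 'sim': {sorted(unknown)}")
        cfg.sim = dict(raw["sim"])
    if "seed" in raw and raw["seed"] is not None:
        cfg.seed = int(raw["seed"])
    return cfg


def write_run_log(out_path: str | Path, config: RunConfig, command: str,
                  extra: dict | None = None) -> None:
    """Write the machine-readable audit log for one command run."""
    from . import __version__

    record = {
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "version": __version__,
        "config": config.resolved(),
        **(extra or {}),
    }
    Path(out_path).write_text(json.dumps(record, indent=2, default=str) + "\n")
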