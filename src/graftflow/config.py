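"""Run configuration: YAML schema, validation, defaults.

A run is fully reproducible from its archived configuration; unknown keys are
rejected by name and schema violations are reported all at once.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigError
from .solver import SimulationConfig
from .units import LPM_TO_M3S, MMHG_TO_PA

__all__ = ["RunConfig", "GeometrySettings", "SolverSettings", "MetricsSettings",
           "load_config"]


class GeometrySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    graft_length_mm: float | None = Field(default=None, gt=0)
    stenosis_center_mm: float | None = Field(default=None, gt=0)
    stenosis_extent_mm: float | None = Field(default=None, gt=0)
    eccentricity: float | None = Field(default=None, ge=0, le=1)

    def overrides(self) -> dict:
        return {k: v for k, v in self.model_dump().items() if v is not None}


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    resolution: int = Field(default=32, ge=8)
    mode: str = Field(default="axisymmetric", pattern="^(axisymmetric|planar)$")
    flows_lpm: list[float] = Field(default=[3.5, 4.5, 5.5])
    outlet_pressure_mmhg: float = 100.0
    cfl: float = Field(default=0.5, gt=0, le=1)
    time_step_s: float | None = Field(default=None, gt=0)
    washout_time_s: float | None = Field(default=None, gt=0)
    sampling_time_s: float = Field(default=1.0, gt=0)
    sample_interval_s: float = Field(default=5e-3, gt=0)

    def to_simulation_config(self, flow_lpm: float) -> SimulationConfig:
        return SimulationConfig(
            inlet_flow_rate=flow_lpm * LPM_TO_M3S,
            outlet_reference_pressure=self.outlet_pressure_mmhg * MMHG_TO_PA,
            grid_resolution=self.resolution,
            mode=self.mode,
            cfl=self.cfl,
            time_step=self.time_step_s,
            washout_time=self.washout_time_s,
            sampling_time=self.sampling_time_s,
            sample_interval=self.sample_interval_s,
        )


class MetricsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    plane_count: int = Field(default=10, ge=1)
    plane_spacing_mm: float = Field(default=5.0, gt=0)
    peak_velocity_mode: str = Field(default="time-mean",
                                    pattern="^(time-mean|instantaneous)$")


class RunConfig(BaseModel):
    """Top-level configuration for a sweep or single run."""

    model_config = ConfigDict(extra="forbid")

    case: int = Field(ge=1, le=2)
    severities: list[str] = Field(default=["OS", "AS1", "AS2"])
    geometry: GeometrySettings = Field(default_factory=GeometrySettings)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    metrics: MetricsSettings = Field(default_factory=MetricsSettings)
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @property
    def inlet_flow_rates_m3s(self) -> list[float]:
        return [f * LPM_TO_M3S for f in self.solver.flows_lpm]

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Fills defaults, rejects unknown keys by name and reports every schema
    violation, not just the first.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            if err["type"] == "extra_forbidden":
                lines.append(f"unknown key: {loc}")
            else:
                lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(lines)
        ) from exc
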