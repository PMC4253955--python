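"""Validated run configuration (YAML) for the command-line workflows."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConditionConfig(_Strict):
    label: str
    cycle_period: float = Field(gt=0)
    n_cycles: int = Field(default=3, ge=1)


class PlantConfig(_Strict):
    n_muscles: int = Field(default=8, ge=2)
    n_dofs: int = Field(default=3, ge=1)
    conditions: list[ConditionConfig] = Field(
        default_factory=lambda: [
            ConditionConfig(label="slow", cycle_period=1.25),
            ConditionConfig(label="fast", cycle_period=1.0),
        ]
    )
    noise: float = Field(default=0.0, ge=0)


class GridConfig(_Strict):
    target_dt: float | None = Field(default=0.1, gt=0)
    n_points: dict[str, int] | None = None

    @model_validator(mode="after")
    def _one_of(self):
        if self.target_dt is None and self.n_points is None:
            raise ValueError("grid needs target_dt or n_points")
        return self


class SolverConfig(_Strict):
    scheme: str = "hermite-simpson"
    n_substeps: int = Field(default=4, ge=1)
    max_nfev: int = Field(default=300, ge=1)
    ftol: float = Field(default=1e-10, gt=0)
    xtol: float = Field(default=1e-10, gt=0)
    gtol: float = Field(default=1e-10, gt=0)
    penalty_u: float = Field(default=200.0, gt=0)

    def options(self) -> dict:
        return {"max_nfev": self.max_nfev, "ftol": self.ftol,
                "xtol": self.xtol, "gtol": self.gtol,
                "penalty_u": self.penalty_u}


class ProtocolConfig(_Strict):
    n_starts: int = Field(default=15, ge=1)
    nsyn_min: int = Field(default=3, ge=1)
    nsyn_max: int = Field(default=7, ge=1)
    polish_nfev: int = Field(default=1200, ge=0)
    k_grid: list[float] = Field(
        default_factory=lambda: [0.0, 100.0, 200.0, 300.0, 400.0, 500.0]
    )
    variance_threshold: float = Field(default=0.9, gt=0, le=1)

    @model_validator(mode="after")
    def _range_ok(self):
        if self.nsyn_max < self.nsyn_min:
            raise ValueError("nsyn_max must be >= nsyn_min")
        return self


class RunConfig(_Strict):
    seed: int = 0
    plant: PlantConfig = Field(default_factory=PlantConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; defaults apply when path is None.

    Unknown keys are rejected with a field-level message.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a config back to YAML (round-trips through load_config)."""
    text = yaml.safe_dump(cfg.model_dump(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
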