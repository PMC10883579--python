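"""Run configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .interference import InterferenceConfig
from .mutation import MutationRates
from .population import DEFAULT_DELTA, DEFAULT_RHO, Grid, NutrientField, Population
from .regulation import DEFAULT_AFFINITY_C, DEFAULT_AFFINITY_S, StageTable

__all__ = ["RunConfig", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """All tunable parameters of a run, defaulting to the model's
    standard conditions."""

    # grid / gradient
    grid_width: int = 45
    grid_height: int = 110
    sectors: int = 11
    influx_min: float = 10.0
    influx_max: float = 110.0
    # dynamics
    rho: float = DEFAULT_RHO
    delta: float = DEFAULT_DELTA
    seed: int = 0
    timesteps: int = 10_000
    # regulation
    B: int = 20
    affinity_c: float = DEFAULT_AFFINITY_C
    affinity_s: float = DEFAULT_AFFINITY_S
    stage_patterns: tuple[str, str, str, str] = ("10001", "11001", "11101", "11011")
    # rates
    mutation: MutationRates = field(default_factory=MutationRates)
    interference: InterferenceConfig = field(default_factory=InterferenceConfig)
    # assay defaults
    assay_T: int = 5000
    assay_window_fraction: float = 0.2

    def stage_table(self) -> StageTable:
        return StageTable.from_strings(*self.stage_patterns)

    def nutrient_field(self) -> NutrientField:
        return NutrientField(
            height=self.grid_height,
            sectors=self.sectors,
            influx_min=self.influx_min,
            influx_max=self.influx_max,
        )

    def sector_influx(self) -> tuple[float, ...]:
        return self.nutrient_field().sector_values

    def build_population(self, seed: int | None = None) -> Population:
        return Population(
            grid=Grid(self.grid_width, self.grid_height),
            fieldspec=self.nutrient_field(),
            rates=self.mutation,
            interference=self.interference,
            table=self.stage_table(),
            rho=self.rho,
            delta=self.delta,
            seed=self.seed if seed is None else seed,
        )

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stage_patterns"] = list(self.stage_patterns)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "mutation" in d and isinstance(d["mutation"], dict):
            d["mutation"] = MutationRates(**d["mutation"])
        if "interference" in d and isinstance(d["interference"], dict):
            d["interference"] = InterferenceConfig(**d["interference"])
        if "stage_patterns" in d:
            d["stage_patterns"] = tuple(d["stage_patterns"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def manifest_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(cfg: RunConfig | dict[str, Any] | None = None) -> RunConfig:
    """Fill defaults, check ranges and geometry; raise ConfigError listing
    every problem found."""
    if cfg is None:
        cfg = RunConfig()
    elif isinstance(cfg, dict):
        try:
            cfg = RunConfig.from_dict(cfg)
        except (TypeError, ValueError) as exc:
            raise ConfigError([str(exc)]) from exc

    errors: list[str] = []
    if cfg.grid_width < 3 or cfg.grid_height < 1:
        errors.append(f"grid {cfg.grid_width}x{cfg.grid_height} too small")
    if cfg.sectors < 1:
        errors.append(f"sectors={cfg.sectors} must be >= 1")
    elif cfg.grid_height % cfg.sectors != 0:
        errors.append(f"height {cfg.grid_height} not divisible by {cfg.sectors} sectors")
    if cfg.influx_min <= 0 or cfg.influx_max < cfg.influx_min:
        errors.append(f"bad influx range [{cfg.influx_min}, {cfg.influx_max}]")
    if cfg.rho <= 0:
        errors.append(f"rho={cfg.rho} must be positive")
    if not (0.0 <= cfg.delta <= 1.0):
        errors.append(f"delta={cfg.delta} outside [0, 1]")
    if cfg.B < 1:
        errors.append(f"B={cfg.B} must be >= 1")
    if cfg.affinity_c <= 0 or not (0.0 < cfg.affinity_s < 1.0):
        errors.append(f"bad affinity constants c={cfg.affinity_c}, s={cfg.affinity_s}")
    try:
        cfg.stage_table()
    except ValueError as exc:
        errors.append(f"stage table: {exc}")
    # rate dataclasses validate themselves on construction; re-check dicts
    for name, value in dataclasses.asdict(cfg.mutation).items():
        if not (0.0 <= value <= 1.0):
            errors.append(f"mutation.{name}={value} outside [0, 1]")
    if not (0.0 <= cfg.interference.leakage_rate <= 1.0):
        errors.append(f"leakage.rate={cfg.interference.leakage_rate} outside [0, 1]")
    if not (0.0 <= cfg.interference.transfer_rate <= 1.0):
        errors.append(f"transfer.rate={cfg.interference.transfer_rate} outside [0, 1]")
    if not (0.0 < cfg.assay_window_fraction <= 1.0):
        errors.append(f"assay_window_fraction={cfg.assay_window_fraction} outside (0, 1]")
    if errors:
        raise ConfigError(errors)
    return cfg
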