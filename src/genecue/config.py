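"""Run configuration: schema, validation, TOML/JSON loading and round-trip.

A run is described by a mode (``gradient``, ``equilibrium``, ``region``,
``sweep``, ``simulate`` or ``info``), the model parameters, and mode-specific
settings.  Defaults reproduce the reference parameter set (N1=20, N2=2,
W=0.5, b=3.0, c=1.5, equal capacities, symmetric migration).  Unknown keys
are rejected with field-level messages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    DispersalConfig,
    GameParams,
    HabitatConfig,
    ModelParams,
)

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]

MODES = ("gradient", "equilibrium", "region", "sweep", "simulate", "info")
STOCHASTIC_MODES = ("simulate", "info")


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass(frozen=True)
class ModelSection:
    N: tuple[int, int] = (20, 2)
    capacity: tuple[int, int] = (2000, 2000)
    W: tuple[float, float] = (0.5, 0.5)
    b: tuple[float, float] = (3.0, 3.0)
    c: tuple[float, float] = (1.5, 1.5)
    m: float = 0.05
    rho: float = 0.0

    def to_params(self) -> ModelParams:
        try:
            return ModelParams(
                game=GameParams(W=self.W, b=self.b, c=self.c),
                habitats=HabitatConfig(N=self.N, capacity=self.capacity),
                dispersal=DispersalConfig.symmetric(self.m, self.rho),
            )
        except ValueError as exc:
            raise ConfigError(f"model: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one command-line run."""

    mode: str
    seed: int | None = None
    out: str = "results"
    verbosity: str = "INFO"
    model: ModelSection = field(default_factory=ModelSection)
    # gradient / equilibrium
    z1: float = 0.2
    z2: float = 0.7
    # region
    grid_step: float = 0.02
    # sweep
    m_values: tuple[float, ...] = (0.01, 0.05, 0.10)
    rho_values: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5)
    # simulate / info
    architecture: str = "A"
    cycles: int = 5000
    replicates: int = 1
    record_every: int = 50
    scale: str = "test"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode in STOCHASTIC_MODES and self.seed is None:
            raise ConfigError(f"mode {self.mode!r} requires a seed")
        if self.architecture not in ("A", "B", "C", "D"):
            raise ConfigError("architecture must be one of A, B, C, D")
        if not 0.0 < self.grid_step <= 0.1:
            raise ConfigError("grid_step must lie in (0, 0.1]")
        if self.scale not in ("test", "paper"):
            raise ConfigError("scale must be 'test' or 'paper'")
        if self.cycles < 1 or self.replicates < 1 or self.record_every < 1:
            raise ConfigError("cycles, replicates, record_every must be >= 1")
        for zname in ("z1", "z2"):
            v = getattr(self, zname)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{zname} must lie in [0, 1]")

    @property
    def params(self) -> ModelParams:
        model = self.model
        if self.scale == "paper":
            model = dataclasses.replace(model, capacity=(20000, 20000))
        return model.to_params()

    @property
    def sim_cycles(self) -> int:
        return 40000 if self.scale == "paper" else self.cycles

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        model_data = data.pop("model", {})
        _check_keys(model_data, ModelSection, "model")
        _check_keys(data, cls, "top level")
        try:
            model = ModelSection(
                **{k: _tuplify(v) for k, v in model_data.items()}
            )
        except TypeError as exc:
            raise ConfigError(f"model section: {exc}") from exc
        data = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(model=model, **data)


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _check_keys(data: dict, cls, where: str) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a table/object")
    allowed = {f.name for f in dataclasses.fields(cls)} - {"model"}
    unknown = set(data) - allowed - ({"model"} if where == "top level" else set())
    if unknown:
        raise ConfigError(
            f"{where}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import tomllib

        data = tomllib.loads(text)
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as JSON (loadable by :func:`load_config`)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
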