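"""Experiment configuration: YAML parsing, validation and sweep expansion.

A configuration file has up to four top-level sections — ``field``,
``model`` (with a nested ``social`` block), ``sweep`` and ``out_root`` —
each overriding the corresponding dataclass defaults.  An empty file is a
valid configuration and yields the reference study conditions: the full
stimulus geometry, the shiner-fit zonal parameters, and the 32-point
log-spaced weight grid with 20 replicates over eta in {0.10, 0.25, 0.40}
and N in {8, 16, 32, 64, 128, 256}.

Unknown keys and invariant violations are rejected with the offending
field path.  Sweep cells receive deterministic per-cell seeds derived from
the master seed, so expansions are reproducible and resumable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .lightfield import FieldConfig
from .simulate import ModelConfig
from .social import SocialParams
from .sweep import derive_seed

__all__ = [
    "ConfigError",
    "SweepSpec",
    "ExperimentConfig",
    "default_config",
    "validate_config",
    "config_to_yaml",
    "expand_sweep",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class SweepSpec:
    """Sweep grid: explicit weights or a (count, lo-exponent, hi-exponent) log grid."""

    weights: tuple[float, ...] | None = None
    weight_grid: tuple[float, float, float] | None = (32, -2.0, 3.0)
    sizes: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
    etas: tuple[float, ...] = (0.10, 0.25, 0.40)
    replicates: int = 20

    def __post_init__(self) -> None:
        if self.weights is None and self.weight_grid is None:
            raise ValueError("one of weights / weight_grid is required")
        if self.weight_grid is not None and (
            len(self.weight_grid) != 3 or int(self.weight_grid[0]) < 2
        ):
            raise ValueError("weight_grid must be (count >= 2, lo exponent, hi exponent)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.sizes or any(n < 1 for n in self.sizes):
            raise ValueError("sizes must be positive group sizes")
        if any(not 0 <= e <= 1 for e in self.etas):
            raise ValueError("etas must lie in [0, 1]")

    def resolve_weights(self) -> np.ndarray:
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        count, lo, hi = self.weight_grid
        return np.logspace(lo, hi, int(count))


@dataclass(frozen=True)
class ExperimentConfig:
    field: FieldConfig = dc_field(default_factory=FieldConfig)
    model: ModelConfig = dc_field(default_factory=ModelConfig)
    sweep: SweepSpec = dc_field(default_factory=SweepSpec)
    out_root: str = "runs"


def default_config() -> ExperimentConfig:
    return ExperimentConfig()


_NESTED = {
    "field": FieldConfig,
    "model": ModelConfig,
    "social": SocialParams,
    "sweep": SweepSpec,
}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"{path}.{key}: unknown key")
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def validate_config(text: str) -> ExperimentConfig:
    """Parse and validate YAML text; defaults fill anything unspecified."""
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    known = {"field", "model", "sweep", "out_root"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in (("field", FieldConfig), ("model", ModelConfig), ("sweep", SweepSpec)):
        if section in raw:
            kwargs[section] = _build(cls, raw[section], section)
    if "out_root" in raw:
        kwargs["out_root"] = str(raw["out_root"])
    return ExperimentConfig(**kwargs)


def config_to_yaml(config: ExperimentConfig) -> str:
    """Serialise a configuration; round-trips through :func:`validate_config`."""
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)


def expand_sweep(config: ExperimentConfig, master_seed: int | None = None) -> pd.DataFrame:
    """Full factorial expansion with deterministic per-cell seeds.

    The master seed defaults to ``config.model.seed``.  The field seed is
    shared across (w, N) within each (eta, replicate) cell so a single
    stimulus can back all runs of that cell.
    """
    if master_seed is None:
        master_seed = config.model.seed
    weights = config.sweep.resolve_weights()
    rows = []
    for ei, eta in enumerate(config.sweep.etas):
        for rep in range(config.sweep.replicates):
            fseed = derive_seed(master_seed, 101, ei, rep)
            for ni, n in enumerate(config.sweep.sizes):
                for wi, w in enumerate(weights):
                    rows.append(
                        {
                            "w_index": wi,
                            "w": float(w),
                            "N": int(n),
                            "eta": float(eta),
                            "replicate": rep,
                            "seed": derive_seed(master_seed, 202, ei, rep, ni, wi),
                            "field_seed": fseed,
                        }
                    )
    return pd.DataFrame(rows)
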