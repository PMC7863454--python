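"""Run configuration: YAML schema, validation and round-trip serialization.

A run is fully described by a :class:`RunConfig`: the data source (a CSV path
or a simulation preset), the split specification, the method grid, the
sensitivity variants, the plausibility bounds and the seed. The manifest
written by :func:`gestimpute.runner.run` embeds the serialized config, so a
run is reproducible from its manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, ParameterError
from .evaluation import MethodSpec, SplitSpec, VariantSpec, default_grid

_TOP_KEYS = {"data", "split", "grid", "variants", "bounds", "out_dir", "seed"}
_DATA_KEYS = {"path", "preset", "n_subjects"}
_SPLIT_KEYS = {"window", "anchor", "n_test", "min_measures"}
_VARIANT_KEYS = {"drop_t3", "t3_cutoff", "covariates", "log_scale"}


@dataclass(frozen=True)
class DataSource:
    """Either a long-format CSV path or a named simulation preset."""

    path: Optional[str] = None
    preset: Optional[str] = None
    n_subjects: Optional[int] = None

    def __post_init__(self):
        if (self.path is None) == (self.preset is None):
            raise ConfigError("data must specify exactly one of 'path' or 'preset'")
        if self.preset is not None and self.preset not in ("study1", "study2"):
            raise ConfigError(f"unknown preset {self.preset!r}")

    def to_dict(self) -> dict:
        if self.path is not None:
            return {"path": self.path}
        d = {"preset": self.preset}
        if self.n_subjects is not None:
            d["n_subjects"] = self.n_subjects
        return d


@dataclass(frozen=True)
class RunConfig:
    data: DataSource
    split: SplitSpec = SplitSpec()
    grid: tuple[MethodSpec, ...] = field(default_factory=lambda: tuple(default_grid()))
    variants: VariantSpec = VariantSpec()
    bounds: tuple[float, float] = (30.0, 120.0)
    out_dir: str = "gestimpute_out"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "data": self.data.to_dict(),
            "split": {
                k: v for k, v in self.split.to_dict().items() if k != "seed"
            },
            "grid": [m.to_dict() for m in self.grid],
            "variants": self.variants.to_dict(),
            "bounds": list(self.bounds),
            "out_dir": self.out_dir,
            "seed": self.seed,
        }


def parse_config_dict(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a plain mapping; unknown keys fail."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "data" not in raw:
        raise ConfigError("configuration must name a 'data' source")

    data_raw = raw["data"]
    if isinstance(data_raw, str):
        data = DataSource(path=data_raw)
    elif isinstance(data_raw, dict):
        unknown = set(data_raw) - _DATA_KEYS
        if unknown:
            raise ConfigError(f"unknown data keys: {sorted(unknown)}")
        data = DataSource(**data_raw)
    else:
        raise ConfigError("'data' must be a path string or a mapping")

    split_raw = dict(raw.get("split") or {})
    unknown = set(split_raw) - _SPLIT_KEYS
    if unknown:
        raise ConfigError(f"unknown split keys: {sorted(unknown)}")
    if "window" in split_raw:
        split_raw["window"] = tuple(split_raw["window"])
    try:
        split = SplitSpec(**split_raw)
    except ParameterError as exc:
        raise ConfigError(f"invalid split: {exc}") from exc

    grid_raw = raw.get("grid")
    try:
        grid = (
            tuple(default_grid())
            if grid_raw is None
            else tuple(MethodSpec.from_dict(d) for d in grid_raw)
        )
    except ParameterError as exc:
        raise ConfigError(f"invalid grid: {exc}") from exc
    if not grid:
        raise ConfigError("grid must contain at least one method")

    var_raw = dict(raw.get("variants") or {})
    unknown = set(var_raw) - _VARIANT_KEYS
    if unknown:
        raise ConfigError(f"unknown variant keys: {sorted(unknown)}")
    if "covariates" in var_raw:
        var_raw["covariates"] = tuple(var_raw["covariates"])
    variants = VariantSpec(**var_raw)

    bounds = tuple(raw.get("bounds") or (30.0, 120.0))
    if len(bounds) != 2 or bounds[0] >= bounds[1]:
        raise ConfigError("bounds must be (min_kg, max_kg) with min < max")

    return RunConfig(
        data=data,
        split=split,
        grid=grid,
        variants=variants,
        bounds=(float(bounds[0]), float(bounds[1])),
        out_dir=str(raw.get("out_dir", "gestimpute_out")),
        seed=int(raw.get("seed", 0)),
    )


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError(f"empty configuration file: {path}")
    return parse_config_dict(raw)


def serialize_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)
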