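"""Run configuration: a single YAML/JSON document driving the pipeline.

Defaults reproduce the standard operating settings: 2 km collocation
exclusion, cross-validated ("auto") bandwidth, IDW power 2, 2 km map
resolution.  Unknown keys fail loudly with their dotted path, so typos in
config files cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PathsConfig:
    sensors: str | None = None      # default: <out_dir>/sensors.csv
    stations: str | None = None     # default: <out_dir>/stations.csv
    out_dir: str = "pmcal_out"


@dataclass
class CollocationConfig:
    max_distance_m: float = 2000.0


@dataclass
class CalibrationConfig:
    bandwidth_m: float | str = "auto"       # meters, or "auto" for LOO-CV
    bandwidth_candidates: list[float] | None = None
    covariates: list[str] = field(default_factory=list)  # beyond sensor pm25
    ridge_epsilon: float = 1e-8


@dataclass
class MappingConfig:
    resolution_m: float = 2000.0
    power: float = 2.0
    padding_m: float = 0.0
    max_radius_m: float | None = None


@dataclass
class SyntheticConfig:
    preset: str = "default"   # default | homogeneous | linear_slope | exclusion
    overrides: dict = field(default_factory=dict)  # SyntheticScenario fields


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    collocation: CollocationConfig = field(default_factory=CollocationConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    log_level: str = "INFO"

    @property
    def sensors_path(self) -> Path:
        return Path(self.paths.sensors or Path(self.paths.out_dir) / "sensors.csv")

    @property
    def stations_path(self) -> Path:
        return Path(self.paths.stations or Path(self.paths.out_dir) / "stations.csv")

    @property
    def out_dir(self) -> Path:
        return Path(self.paths.out_dir)

    def to_dict(self) -> dict:
        def conv(obj):
            if is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [conv(x) for x in obj]
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj
        return conv(self)


def _build(cls, doc: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in doc.items():
        if key not in known:
            raise ConfigurationError(f"unknown config key '{path}{key}'")
        ftype = known[key].type
        sub = {"paths": PathsConfig, "collocation": CollocationConfig,
               "calibration": CalibrationConfig, "mapping": MappingConfig,
               "synthetic": SyntheticConfig}.get(key)
        if sub is not None:
            if not isinstance(value, dict):
                raise ConfigurationError(f"config section {path}{key} must be a mapping")
            kwargs[key] = _build(sub, value, f"{path}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML (or JSON — YAML superset) config file; ``overrides``
    replace top-level or dotted keys (e.g. ``calibration__bandwidth_m``)."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config root of {path} must be a mapping")
    cfg = _build(RunConfig, doc, "")
    for key, value in overrides.items():
        if value is None:
            continue
        parts = key.split("__")
        target = cfg
        for p in parts[:-1]:
            target = getattr(target, p)
        if not hasattr(target, parts[-1]):
            raise ConfigurationError(f"unknown override {'.'.join(parts)!r}")
        setattr(target, parts[-1], value)
    return cfg
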