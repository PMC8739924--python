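"""Pipeline configuration: a single YAML file with per-stage sections.

Unknown keys are rejected with an error naming the key, so typos never
silently fall back to defaults. The configuration round-trips losslessly
through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigError

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class SimulateSection:
    n_per_group: list = field(default_factory=lambda: [10, 10, 10])
    duration_s: float = 20.0
    fs: float = 720.0
    noise_sd: float = 0.15
    drift_amplitude: float = 1.0
    drift_freq_hz: float = 0.2
    period_cv: float = 0.03
    subject_cv: float = 0.05


@dataclass
class PreprocessSection:
    lowpass_hz: float = 20.0
    highpass_hz: float = 0.5
    filter_order: int = 4


@dataclass
class FiducialSection:
    w1_fraction: float = 1.0 / 3.0
    w2_fraction: float = 2.0 / 3.0
    min_cycles: int = 10
    min_period_s: float = 0.4
    max_period_s: float = 1.5
    min_amplitude: float = 0.5


@dataclass
class MseSection:
    max_scale: int = 5
    m: int = 2
    r_factor: float = 0.15


@dataclass
class StatsSection:
    alpha: float = 0.05
    bonferroni: bool = False


@dataclass
class ClassifySection:
    folds: int = 10
    knn_k: int = 5
    rf_trees: int = 500


@dataclass
class PipelineConfig:
    outdir: str = "pulsewave_out"
    seed: int = 0
    simulate: SimulateSection = field(default_factory=SimulateSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    fiducial: FiducialSection = field(default_factory=FiducialSection)
    mse: MseSection = field(default_factory=MseSection)
    stats: StatsSection = field(default_factory=StatsSection)
    classify: ClassifySection = field(default_factory=ClassifySection)

    def validate(self) -> None:
        if self.simulate.fs <= 0:
            raise ConfigError("simulate.fs must be positive")
        if not 0 < self.fiducial.w2_fraction < 1 or not 0 < self.fiducial.w1_fraction < 1:
            raise ConfigError("fiducial width fractions must lie in (0, 1)")
        if self.mse.max_scale < 1 or self.mse.m < 1 or self.mse.r_factor <= 0:
            raise ConfigError("mse section values out of range")
        if not 0 < self.stats.alpha < 1:
            raise ConfigError("stats.alpha must lie in (0, 1)")
        if self.classify.folds < 2:
            raise ConfigError("classify.folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _build_section(cls, data: dict, prefix: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config key {prefix}{sorted(unknown)[0]!r}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    sections = {
        "simulate": SimulateSection,
        "preprocess": PreprocessSection,
        "fiducial": FiducialSection,
        "mse": MseSection,
        "stats": StatsSection,
        "classify": ClassifySection,
    }
    kwargs = {}
    for name, cls in sections.items():
        raw = data.pop(name, {}) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, raw, f"{name}.")
    top_valid = {"outdir", "seed"}
    unknown = set(data) - top_valid
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
    cfg = PipelineConfig(**{**data, **kwargs})
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def config_hash(cfg: PipelineConfig) -> str:
    canonical = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
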