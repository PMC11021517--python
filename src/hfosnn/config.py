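"""Declarative pipeline configuration.

One YAML file holds every knob of every stage — filtering, ADM tuning,
mismatch, evolutionary optimization, detection rules, outcome
statistics, reconstruction and the synthetic generator — plus the
global seed. Defaults live on the stage dataclasses themselves; the
shipped ``default_config.yaml`` is generated from them (and a test pins
the two together), so each constant has exactly one home. Unknown keys
are rejected, not ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .adm import DELTA_MIN_DEFAULT, EEG_TUNING, HFO_TUNING
from .detection import DetectionRules
from .evolution import EvolutionConfig, ScoreWeights
from .preprocessing import DEFAULT_BLOCK, DEFAULT_ORDER, EEG_BAND, HFO_BAND
from .reconstruction import RlsConfig, RnnConfig
from .snn import DEFAULT_EEG_PARAMS, DEFAULT_HFO_PARAMS, MismatchModel, NeuronParams
from .synthetic import SyntheticConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config", "default_config_dict", "dump_config"]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


@dataclass(frozen=True)
class FilterConfig:
    order: int = DEFAULT_ORDER
    block_size: int = DEFAULT_BLOCK
    eeg_band: tuple[float, float] = EEG_BAND
    hfo_band: tuple[float, float] = HFO_BAND


@dataclass(frozen=True)
class AdmConfig:
    tuning_duration: float = EEG_TUNING.tuning_duration  # 5 s for both bands
    eeg_window_len: float = EEG_TUNING.window_len
    hfo_window_len: float = HFO_TUNING.window_len
    eeg_percentile: float = EEG_TUNING.percentile
    hfo_percentile: float = HFO_TUNING.percentile
    delta_min: float = DELTA_MIN_DEFAULT
    eeg_refractory: float = 0.0
    hfo_refractory: float = 0.0


@dataclass(frozen=True)
class SnnConfig:
    dt: float = 1e-4
    mismatch_cv: float = 0.20
    eeg: NeuronParams = DEFAULT_EEG_PARAMS
    hfo: NeuronParams = DEFAULT_HFO_PARAMS


@dataclass(frozen=True)
class StatsConfig:
    rate_threshold: float = 1.0  # events/min


@dataclass(frozen=True)
class ReconstructionConfig:
    rnn: RnnConfig = RnnConfig()
    rls: RlsConfig = RlsConfig()
    max_span: float = 0.500
    margin: float = 0.100


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    filter: FilterConfig = FilterConfig()
    adm: AdmConfig = AdmConfig()
    snn: SnnConfig = SnnConfig()
    evolution: EvolutionConfig = EvolutionConfig()
    detection: DetectionRules = DetectionRules()
    stats: StatsConfig = StatsConfig()
    reconstruction: ReconstructionConfig = ReconstructionConfig()
    synthetic: SyntheticConfig = SyntheticConfig()

    def mismatch(self) -> MismatchModel:
        return MismatchModel(cv=self.snn.mismatch_cv, seed=self.seed)


_NESTED = {
    FilterConfig, AdmConfig, SnnConfig, StatsConfig, ReconstructionConfig,
    EvolutionConfig, DetectionRules, SyntheticConfig, NeuronParams, ScoreWeights,
    RnnConfig, RlsConfig, PipelineConfig,
}


def _build(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        default = fields[name].default
        factory = fields[name].default_factory
        template = default if default is not dataclasses.MISSING else (
            factory() if factory is not dataclasses.MISSING else None
        )
        if type(template) in _NESTED:
            kwargs[name] = _build(type(template), value, f"{path}{name}.")
        elif isinstance(template, tuple) and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def _to_dict(obj):
    if type(obj) in _NESTED:
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def default_config_dict() -> dict:
    return _to_dict(PipelineConfig())


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML pipeline config; ``None`` loads the shipped defaults."""
    if path is None:
        with resources.as_file(resources.files("hfosnn").joinpath("default_config.yaml")) as p:
            text = p.read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return _build(PipelineConfig, data)


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(_to_dict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
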