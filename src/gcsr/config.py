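"""Pipeline configuration: strict YAML schema over plain dataclasses."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .task import ParticipantModel, SessionConfig

__all__ = ["PreprocessConfig", "SpectralConfig", "SynthConfig", "StatsConfig",
           "PipelineConfig", "load_config", "dump_config"]


@dataclass
class SynthConfig:
    boost_uv: float = 8.0
    null_group: str = "GAD_TR"
    centre_freq_hz: float = 8.0
    bandwidth_hz: float = 0.0
    background_scale_uV: float = 10.0
    background_exponent: float = 1.0
    blink_rate_hz: float = 0.10
    blink_amplitude_uV: float = 120.0
    design: str = "default"  # "default" (44 subjects) or "anxiety" (18)

    def __post_init__(self) -> None:
        if self.design not in ("default", "anxiety"):
            raise ValueError("design must be 'default' or 'anxiety'")
        for name in ("background_scale_uV", "blink_rate_hz", "blink_amplitude_uV"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PreprocessConfig:
    low_hz: float = 1.0
    high_hz: float = 36.0
    target_hz: float = 128.0
    blink_threshold_uV: float = 75.0
    peak_to_peak_uV: float = 150.0
    centring: str = "period"

    def __post_init__(self) -> None:
        for name in ("low_hz", "high_hz", "target_hz", "blink_threshold_uV",
                     "peak_to_peak_uV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.centring not in ("period", "onset"):
            raise ValueError("centring must be 'period' or 'onset'")


@dataclass
class SpectralConfig:
    channel: str = "F8"
    blocks: tuple[int, ...] = (2, 3)
    smooth: bool = True
    log_domain: bool = True


@dataclass
class StatsConfig:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "gcsr_out"
    task: SessionConfig = field(default_factory=SessionConfig)
    participant: ParticipantModel = field(default_factory=ParticipantModel)
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


_SECTIONS = {
    "task": SessionConfig,
    "participant": ParticipantModel,
    "synth": SynthConfig,
    "preprocess": PreprocessConfig,
    "spectral": SpectralConfig,
    "stats": StatsConfig,
}


def _build(cls, mapping: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    kwargs = dict(mapping)
    if cls is SpectralConfig and "blocks" in kwargs:
        kwargs["blocks"] = tuple(kwargs["blocks"])
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    top_known = {"seed", "out_dir"} | set(_SECTIONS)
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        kwargs["out_dir"] = str(raw["out_dir"])
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw[name] or {}
            if not isinstance(section, dict):
                raise ValueError(f"section {name} must be a mapping")
            kwargs[name] = _build(cls, section, name)
    return PipelineConfig(**kwargs)


def dump_config(cfg: PipelineConfig, path) -> None:
    """Echo the fully resolved configuration to YAML."""
    def as_dict(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: as_dict(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(as_dict(cfg), sort_keys=False))
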