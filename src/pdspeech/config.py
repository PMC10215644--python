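"""Declarative pipeline configuration.

A single YAML file with sections ``synth``, ``wiener``, ``vad``,
``features``, ``spectro``, ``classifier`` and ``seed``; every constant of
the assessment protocol (20 ms framing, 1/10 energy threshold, 16 kHz LPC
rate, learning rate 0.005, batch 128, 224 px images, 0.2/0.2 split
fractions) surfaces as a named key whose default is the protocol value.
Unknown keys are rejected to catch typos.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classifier import TrainConfig
from .spectro import SpectroParams
from .wiener import WienerConfig

__all__ = ["VadSettings", "FeatureSettings", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class VadSettings:
    frame_len_ms: float = 20.0
    threshold_ratio: float = 0.1


@dataclass(frozen=True)
class FeatureSettings:
    frame_len_ms: float = 20.0
    overlap: float = 0.5
    intensity_ref: float = 1e-4
    f0_min: float = 75.0
    f0_max: float = 400.0
    lpc_rate: int = 16000
    lpc_order: int = 12
    lpc_bandwidth_max: float = 400.0


@dataclass(frozen=True)
class PipelineConfig:
    vad: VadSettings = field(default_factory=VadSettings)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    wiener: WienerConfig = field(default_factory=WienerConfig)
    spectro: SpectroParams = field(default_factory=SpectroParams)
    classifier: TrainConfig = field(default_factory=TrainConfig)
    spectrogram_kinds: tuple[str, ...] = ("speech", "energy", "mel")
    reduction_k: float = 1.0  # RangeRule width in class standard deviations
    seed: int = 0


def _build(cls, data: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing file or sections fall back to defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {
        "vad": VadSettings,
        "features": FeatureSettings,
        "wiener": WienerConfig,
        "spectro": SpectroParams,
        "classifier": TrainConfig,
    }
    kwargs = {}
    for name, cls in sections.items():
        if name in raw:
            kwargs[name] = _build(cls, raw.pop(name))
    for key in ("spectrogram_kinds", "reduction_k", "seed"):
        if key in raw:
            value = raw.pop(key)
            kwargs[key] = tuple(value) if key == "spectrogram_kinds" else value
    if raw:
        raise ValueError(f"unknown config sections: {sorted(raw)}")
    return PipelineConfig(**kwargs)
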