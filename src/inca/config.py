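"""Serializable configuration for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .events import BlisterConfig, BreathConfig, SegmentationConfig
from .technique import TechniqueConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, fully serializable to YAML/JSON.

    Exactly one input source is used, in this order of precedence:
    ``audio_dir`` (WAV + sidecar files, detected and classified),
    ``log_csv`` (pre-labelled dose log), or a synthetic cohort drawn
    from the generator (``synthetic=True``).
    """

    out_dir: str = "inca_out"
    audio_dir: str | None = None
    log_csv: str | None = None
    clinical_csv: str | None = None
    synthetic: bool = True
    n_subjects: int = 51
    days: int = 84
    prescribed_per_day: int = 2
    error_rate: float = 0.10
    seed: int = 0
    mcid_aqlq: float = 0.5
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    blister: BlisterConfig = field(default_factory=BlisterConfig)
    breath: BreathConfig = field(default_factory=BreathConfig)
    technique: TechniqueConfig = field(default_factory=TechniqueConfig)
    make_plots: bool = True

    def __post_init__(self) -> None:
        for name in ("error_rate", "mcid_aqlq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation"]["band_hz"] = list(d["segmentation"]["band_hz"])
        return d


def _build(d: dict) -> PipelineConfig:
    d = dict(d)
    for key, cls in (
        ("segmentation", SegmentationConfig),
        ("blister", BlisterConfig),
        ("breath", BreathConfig),
        ("technique", TechniqueConfig),
    ):
        if key in d and isinstance(d[key], dict):
            sub = dict(d[key])
            for tup_key in ("band_hz", "peak_band_hz", "precursor_band_hz"):
                if tup_key in sub:
                    sub[tup_key] = tuple(sub[tup_key])
            d[key] = cls(**sub)
    return PipelineConfig(**d)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML (or JSON) config; ``None`` returns the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    return _build(data or {})


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
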