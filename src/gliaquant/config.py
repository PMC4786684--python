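"""Flat analysis configuration shared by the CLI subcommands.

One YAML/JSON document mirrors every CLI flag; flags override config values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    threshold_method: str = "triangle"  # triangle | fixed
    threshold_value: float | None = None
    min_artifact_size: int = 0  # px, components below this are dropped
    sholl_step: float = 5.0  # µm
    sholl_max_radius: float = 60.0  # µm
    pixel_size: float = 1.0  # µm/px
    frame_interval: float = 4.0  # min
    projection_depth: int = 0  # planes per projection (0 = all)
    inner_radius: float = 40.0  # µm, ablation
    outer_radius: float = 80.0  # µm, ablation
    core_exclusion: float = 5.0  # µm, ablation
    min_punctum_px: int = 1  # puncta must be strictly larger
    smooth_sigma: float = 1.0  # px
    stim_frequency: float = 0.05  # Hz
    sampling_rate: float = 2.0  # Hz
    grubbs_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sholl_step",
            "sholl_max_radius",
            "pixel_size",
            "frame_interval",
            "inner_radius",
            "outer_radius",
            "stim_frequency",
            "sampling_rate",
            "grubbs_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.core_exclusion < 0 or self.min_punctum_px < 0 or self.min_artifact_size < 0:
            raise ValueError("sizes must be non-negative")
        if self.inner_radius >= self.outer_radius:
            raise ValueError("inner_radius must be smaller than outer_radius")

    def as_dict(self) -> dict:
        return asdict(self)

    def override(self, **kwargs) -> "AnalysisConfig":
        """A copy with any non-None keyword values replacing config values."""
        data = self.as_dict()
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return AnalysisConfig(**data)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load a flat YAML or JSON config file; missing path gives defaults."""
    if path is None:
        return AnalysisConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if data is None:
        return AnalysisConfig()
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)
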