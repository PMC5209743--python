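"""Run configuration: a flat, YAML-serializable record of every knob.

A run's effective configuration is always written beside its outputs so
any report can be regenerated from the output directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .pipeline import PreprocessConfig
from .texture import TextureConfig


@dataclass
class RunConfig:
    """Effective parameters of one workflow run."""

    # paths
    input_dir: str = ""
    output_dir: str = "chromatex_out"
    # preprocessing
    background_radius: int = 50
    segment_sigma: float = 2.0
    min_area_px: int = 100
    w_green: float = 0.5
    w_red: float = 0.5
    median_kernel: int = 1
    # texture
    n_levels: int = 16
    window: int = 9
    distances: tuple[int, ...] = (1, 2)
    min_pairs: int = 8
    texture_mode: str = "windowed"
    # analytics
    cv_folds: int = 5
    classifier_mode: str = "pc3"
    ppi_mode: str = "axis"
    oci_log_scale: bool = True
    seed: int = 0
    # logging
    log_level: str = "INFO"

    def texture_config(self) -> TextureConfig:
        return TextureConfig(
            n_levels=self.n_levels,
            window=self.window,
            distances=tuple(self.distances),
            min_pairs=self.min_pairs,
            mode=self.texture_mode,
        )

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            background_radius=self.background_radius,
            segment_sigma=self.segment_sigma,
            min_area_px=self.min_area_px,
            w_green=self.w_green,
            w_red=self.w_red,
            median_kernel=self.median_kernel,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["distances"] = list(d["distances"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "distances" in data:
            data = {**data, "distances": tuple(data["distances"])}
        return cls(**data)
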