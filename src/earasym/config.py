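"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import DEFAULT_RESIDUAL_FRACTIONS


@dataclass
class DetectorConfig:
    stages: int = 6
    trees_per_stage: int = 50
    depth: int = 5
    learning_rate: float = 0.5
    feature_pool_size: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.stages < 0 or self.trees_per_stage < 1 or self.depth < 1:
            raise ValueError("detector: stages/trees_per_stage/depth out of range")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("detector.learning_rate must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    n_frames: int = 30
    closure_amplitude: float = 1.0
    head_sway_deg: float = 5.0
    jitter_px: float = 0.3
    n_per_grade: int = 15
    residual_fraction_map: dict = field(
        default_factory=lambda: dict(DEFAULT_RESIDUAL_FRACTIONS))

    def validate(self) -> None:
        if self.n_frames < 1 or self.n_per_grade < 1:
            raise ValueError("generator: n_frames and n_per_grade must be >= 1")
        if self.jitter_px < 0 or self.head_sway_deg < 0:
            raise ValueError("generator: noise parameters must be non-negative")


@dataclass
class CVConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = False

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("cv.k must be >= 2")


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline, with validated defaults."""

    normalize_crop_px: int = 128
    frechet_coupling: str = "eiter_mannila"
    exclusion_nme_threshold: float = 0.08
    classifier_method: str = "nearest_median"
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def validate(self) -> "PipelineConfig":
        if self.normalize_crop_px < 16:
            raise ValueError("normalize_crop_px must be >= 16")
        if self.frechet_coupling not in ("eiter_mannila", "identity"):
            raise ValueError("frechet_coupling must be 'eiter_mannila' or 'identity'")
        if self.exclusion_nme_threshold <= 0:
            raise ValueError("exclusion_nme_threshold must be positive")
        if self.classifier_method not in ("nearest_median", "thresholds", "knn3"):
            raise ValueError(f"unknown classifier_method {self.classifier_method!r}")
        self.detector.validate()
        self.generator.validate()
        self.cv.validate()
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in payload.items():
            if key in ("detector", "generator", "cv") and isinstance(value, dict):
                sub = getattr(cfg, key)
                for k, v in value.items():
                    if not hasattr(sub, k):
                        raise ValueError(f"unknown config key {key}.{k}")
                    if k == "residual_fraction_map":
                        v = {int(g): float(r) for g, r in v.items()}
                    setattr(sub, k, v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg.validate()

    def to_dict(self) -> dict:
        return asdict(self)
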