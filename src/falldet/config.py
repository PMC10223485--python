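"""YAML configuration: one file with ``preprocess:``, ``augment:``,
``model:``, ``train:``, ``split:`` and ``synthetic:`` sections, each mapping
directly onto the corresponding dataclass."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .architecture import EnsembleSpec
from .augmentation import AugmentationConfig
from .preprocessing import PreprocessConfig
from .synthetic_data import SyntheticConfig
from .training import SplitSpec, TrainConfig


def _build(cls, section: dict | None):
    section = dict(section or {})
    valid = {f.name for f in fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}"
        )
    for key in ("head_widths", "recurrent_widths", "test_subjects",
                "transform_probs", "rotation_angle_range", "class_weights",
                "tie_break_priority"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    return cls(**section)


@dataclass
class ExperimentConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: EnsembleSpec = field(default_factory=EnsembleSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


def load_config(path: Path | str | None) -> ExperimentConfig:
    """Load a YAML config; a missing/None path yields all defaults."""
    if path is None:
        return ExperimentConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig(
        preprocess=_build(PreprocessConfig, raw.get("preprocess")),
        augment=_build(AugmentationConfig, raw.get("augment")),
        model=_build(EnsembleSpec, raw.get("model")),
        train=_build(TrainConfig, raw.get("train")),
        split=_build(SplitSpec, raw.get("split")),
        synthetic=_build(SyntheticConfig, raw.get("synthetic")),
    )
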