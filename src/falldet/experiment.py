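"""End-to-end workflow: generate (or load) trials, preprocess with
leakage-free normalization, split subject-wise, train replicates, evaluate.

The ordering matters: test subjects are fixed *before* normalization so the
per-channel statistics are fit only on training-side subjects, then frozen
for everything else — the subject-wise protocol would otherwise leak test
data into the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .architecture import ClassEnsembleNetwork, EnsembleSpec
from .augmentation import AugmentationConfig
from .evaluation import EvaluationReport, evaluation_report
from .io_formats import AnnotatedTrial, BlockDataset, select_channels
from .preprocessing import (
    NormalizationStats,
    PreprocessConfig,
    lowpass_filter,
    preprocess_trials,
)
from .synthetic_data import SyntheticConfig, generate_dataset
from .training import (
    SplitSpec,
    TrainConfig,
    TrainingResult,
    choose_test_subjects,
    make_splits,
    train_replicates,
)


@dataclass
class ExperimentResult:
    train: BlockDataset
    val: BlockDataset
    test: BlockDataset
    runs: list[TrainingResult]
    report: EvaluationReport
    test_subjects: tuple[str, ...]

    @property
    def mean_test_sensitivity(self) -> pd.Series:
        col = "sensitivity_mean" if "sensitivity_mean" in self.report.metrics else "sensitivity"
        return self.report.metrics[col]


def prepare_blocks(
    trials: Sequence[AnnotatedTrial],
    pre_cfg: PreprocessConfig,
    test_subjects: set[str],
) -> BlockDataset:
    """Filter, normalize (training-subject statistics only), segment."""
    train_side = {
        t.trial.subject_id for t in trials
        if t.trial.subject_id not in test_subjects
    }
    # fit stats on filtered training-subject trials, freeze for everyone
    stats = NormalizationStats.from_trials(
        lowpass_filter(t, pre_cfg)
        for t in trials if t.trial.subject_id in train_side
    )
    return preprocess_trials(trials, pre_cfg, stats=stats)


def run_experiment(
    trials: Sequence[AnnotatedTrial],
    pre_cfg: PreprocessConfig | None = None,
    spec: EnsembleSpec | None = None,
    split: SplitSpec | None = None,
    train_cfg: TrainConfig | None = None,
    aug_cfg: AugmentationConfig | None = None,
    seeds: Sequence[int] = (0, 1, 2),
) -> ExperimentResult:
    """Run the full protocol on an annotated trial collection."""
    pre_cfg = pre_cfg or PreprocessConfig()
    split = split or SplitSpec()
    train_cfg = train_cfg or TrainConfig()

    # training input is six-dimensional: first accelerometer + gyroscope
    trials = [
        AnnotatedTrial(select_channels(t.trial), t.labels)
        if t.trial.n_channels > 6 else t
        for t in trials
    ]

    # resolve test subjects on a provisional (label-only) dataset first
    provisional = preprocess_trials(trials, pre_cfg)
    test_subjects = choose_test_subjects(provisional, split)
    dataset = prepare_blocks(trials, pre_cfg, set(test_subjects))

    block_spec = spec or EnsembleSpec(
        input_shape=(pre_cfg.block_width, dataset.X.shape[2])
    )
    fixed_split = SplitSpec(
        test_subjects=test_subjects,
        train_val_ratio=split.train_val_ratio,
        split_seed=split.split_seed,
    )
    train_ds, val_ds, test_ds = make_splits(dataset, fixed_split)

    def build(seed: int) -> ClassEnsembleNetwork:
        return ClassEnsembleNetwork(block_spec, np.random.default_rng(int(seed)))

    runs = train_replicates(
        build, train_ds, val_ds, train_cfg, aug_cfg, seeds=seeds
    )
    report = evaluation_report([r.model for r in runs], test_ds)
    return ExperimentResult(
        train=train_ds, val=val_ds, test=test_ds,
        runs=runs, report=report, test_subjects=tuple(test_subjects),
    )


def easy_preset_experiment(
    seeds: Sequence[int] = (0, 1, 2),
    max_epochs: int = 30,
    synth_cfg: SyntheticConfig | None = None,
    n_test_young: int = 1,
    n_test_elderly: int = 1,
    split_seed: int = 0,
) -> ExperimentResult:
    """The desk-scale end-to-end learning check on the easy preset.

    Six subjects (four young, two elderly) with one young and one elderly
    held out for testing; the default architecture trained for up to 30
    epochs per replicate seed with online augmentation.
    """
    cfg = synth_cfg or SyntheticConfig.easy()
    trials = generate_dataset(cfg).trials
    return run_experiment(
        trials,
        split=SplitSpec(
            n_test_young=n_test_young, n_test_elderly=n_test_elderly,
            split_seed=split_seed,
        ),
        train_cfg=TrainConfig(max_epochs=max_epochs),
        aug_cfg=AugmentationConfig(),
        seeds=seeds,
    )
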