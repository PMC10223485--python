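"""Low-pass filtering, normalization, sliding-window segmentation, and
majority block labeling.

The pipeline follows the usual treatment of waist-worn IMU recordings:
a zero-phase Butterworth low-pass removes high-frequency noise, channels
are normalized with statistics frozen on the training subjects, and each
trial is cut into fixed-width overlapping blocks (default 256 samples,
50% overlap; 1.28 s at 200 Hz) that each carry a single event label chosen
by majority vote with a severity tie-break (FALL > PRE_FALL > NON_FALL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .io_formats import AnnotatedTrial, BlockDataset
from .labels import DEFAULT_TIE_BREAK, ClassLabel


class FilteringError(ValueError):
    """Trial too short for the zero-phase filter's padding requirement."""


@dataclass
class PreprocessConfig:
    """Knobs for the filtering/normalization/segmentation stage.

    ``normalization`` modes: ``zscore_clip`` (z-score then hard clip to
    [-1, +1], the default), ``minmax`` (affine map of the training range to
    [-1, +1]), ``zscore_tanh`` (tanh-squashed z-score).
    """

    filter_order: int = 4
    filter_cutoff_hz: float = 5.0
    block_width: int = 256
    overlap_fraction: float = 0.5
    normalization: str = "zscore_clip"
    tie_break_priority: tuple[ClassLabel, ...] = field(
        default_factory=lambda: DEFAULT_TIE_BREAK
    )

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter_cutoff_hz must be positive")
        if self.block_width < 2:
            raise ValueError("block_width must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.normalization not in ("zscore_clip", "minmax", "zscore_tanh"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def stride(self) -> int:
        s = int(round(self.block_width * (1.0 - self.overlap_fraction)))
        return max(s, 1)


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def lowpass_filter(trial: AnnotatedTrial, cfg: PreprocessConfig) -> AnnotatedTrial:
    """Zero-phase (forward-backward) Butterworth low-pass, per channel.

    Zero-phase application keeps samples aligned with their per-timestep
    labels.  Requires ``T > 3 * (filter_order + 1)`` (filtfilt padding).
    """
    fs = trial.trial.sample_rate_hz
    if cfg.filter_cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {cfg.filter_cutoff_hz} Hz must be below Nyquist {fs / 2} Hz"
        )
    x = trial.trial.samples
    padlen = 3 * (cfg.filter_order + 1)
    if x.shape[0] <= padlen:
        raise FilteringError(
            f"trial of {x.shape[0]} samples too short for order-"
            f"{cfg.filter_order} zero-phase filtering (needs > {padlen})"
        )
    sos = signal.butter(
        cfg.filter_order, cfg.filter_cutoff_hz, btype="low", fs=fs, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, x, axis=0)
    return trial.with_samples(filtered)


def butterworth_gain(cfg: PreprocessConfig, freq_hz: float, fs: float = 200.0) -> float:
    """Closed-form magnitude response of the zero-phase filter at ``freq_hz``.

    Forward-backward filtering squares the single-pass Butterworth magnitude
    ``|H(f)| = 1 / sqrt(1 + (f/fc)^(2n))``.
    """
    single = 1.0 / np.sqrt(1.0 + (freq_hz / cfg.filter_cutoff_hz) ** (2 * cfg.filter_order))
    return float(single ** 2)


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-channel statistics, fit on training-subject trials only."""

    mean: np.ndarray
    std: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    zero_std_channels: tuple[int, ...] = ()

    @classmethod
    def from_trials(cls, trials: Iterable[AnnotatedTrial]) -> "NormalizationStats":
        stacked = np.concatenate([t.trial.samples for t in trials], axis=0)
        if stacked.size == 0:
            raise ValueError("cannot fit normalization statistics on no data")
        std = stacked.std(axis=0)
        zero = tuple(int(i) for i in np.nonzero(std == 0.0)[0])
        std = np.where(std == 0.0, 1.0, std)  # degenerate channel: sigma := 1
        return cls(
            mean=stacked.mean(axis=0),
            std=std,
            minimum=stacked.min(axis=0),
            maximum=stacked.max(axis=0),
            zero_std_channels=zero,
        )


def normalize(
    trial: AnnotatedTrial,
    stats: NormalizationStats,
    cfg: PreprocessConfig,
) -> AnnotatedTrial:
    """Map samples into [-1, +1] using frozen training statistics."""
    x = trial.trial.samples
    if cfg.normalization == "zscore_clip":
        z = (x - stats.mean) / stats.std
        out = np.clip(z, -1.0, 1.0)
    elif cfg.normalization == "zscore_tanh":
        out = np.tanh((x - stats.mean) / stats.std)
    else:  # minmax
        span = stats.maximum - stats.minimum
        span = np.where(span == 0.0, 1.0, span)
        out = np.clip(2.0 * (x - stats.minimum) / span - 1.0, -1.0, 1.0)
    return trial.with_samples(out)


# --------------------------------------------------------------------------
# Segmentation and block labeling
# --------------------------------------------------------------------------

@dataclass
class Block:
    """One fixed-width window of a trial with its majority label."""

    samples: np.ndarray         # (W, C)
    label: ClassLabel
    subject_id: str
    source_trial: str
    start_index: int
    subject_group: str = "young"


def label_block(
    window_labels: Sequence[int] | np.ndarray,
    cfg: PreprocessConfig | None = None,
) -> ClassLabel:
    """Majority label of a window; ties go to the more severe event."""
    priority = (cfg.tie_break_priority if cfg is not None else DEFAULT_TIE_BREAK)
    counts = np.bincount(np.asarray(window_labels, dtype=np.int64),
                         minlength=len(ClassLabel))
    best = counts.max()
    for cls in priority:
        if counts[int(cls)] == best:
            return cls
    raise RuntimeError("unreachable: tie-break priority must cover all classes")


def segment_blocks(trial: AnnotatedTrial, cfg: PreprocessConfig) -> list[Block]:
    """Cut a trial into stride-aligned windows ``[s, s+W)``.

    Returns an empty list (not an error) when the trial is shorter than one
    window; trailing partial windows are discarded.
    """
    W, stride = cfg.block_width, cfg.stride
    T = trial.trial.n_samples
    blocks: list[Block] = []
    for start in range(0, T - W + 1, stride):
        window = trial.trial.samples[start:start + W]
        lab = label_block(trial.labels[start:start + W], cfg)
        blocks.append(Block(
            samples=window,
            label=lab,
            subject_id=trial.trial.subject_id,
            source_trial=trial.trial.trial_id,
            start_index=start,
            subject_group=trial.trial.subject_group,
        ))
    return blocks


def blocks_to_dataset(blocks: Sequence[Block]) -> BlockDataset:
    """Stack segmented blocks into the array-backed dataset container."""
    if not blocks:
        raise ValueError("cannot build a dataset from zero blocks")
    return BlockDataset(
        X=np.stack([b.samples for b in blocks]),
        y=np.asarray([int(b.label) for b in blocks], dtype=np.int8),
        subjects=np.asarray([b.subject_id for b in blocks], dtype=object),
        groups=np.asarray([b.subject_group for b in blocks], dtype=object),
        trial_ids=np.asarray([b.source_trial for b in blocks], dtype=object),
        starts=np.asarray([b.start_index for b in blocks], dtype=np.int64),
    )


def preprocess_trials(
    trials: Sequence[AnnotatedTrial],
    cfg: PreprocessConfig,
    stats: NormalizationStats | None = None,
    stats_subjects: set[str] | None = None,
) -> BlockDataset:
    """Filter -> normalize -> segment a trial collection into one dataset.

    ``stats_subjects`` restricts the normalization fit to those subjects
    (the training side of a subject-wise split); alternatively pass frozen
    ``stats`` directly.
    """
    filtered = [lowpass_filter(t, cfg) for t in trials]
    if stats is None:
        fit_pool = (
            [t for t in filtered if t.trial.subject_id in stats_subjects]
            if stats_subjects is not None else filtered
        )
        if not fit_pool:
            raise ValueError("no trials available to fit normalization stats")
        stats = NormalizationStats.from_trials(fit_pool)
    blocks: list[Block] = []
    for t in filtered:
        blocks.extend(segment_blocks(normalize(t, stats, cfg), cfg))
    return blocks_to_dataset(blocks)
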