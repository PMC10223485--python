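"""Reading SisFall-style trial files, per-sample annotations, and the
HDF5-backed block dataset container.

A SisFall-style trial is one plain-text file per (activity, subject, trial)
named ``<activity>_<subject>_R<trial>.txt`` whose rows are comma- (or
semicolon-) separated integer ADC counts for nine channels: first tri-axial
accelerometer, tri-axial gyroscope, second tri-axial accelerometer, sampled
at 200 Hz.  Counts are converted to physical units (g, deg/s) with linear
per-sensor scale factors derived from each sensor's range and bit depth.

Annotations give one integer label per timestep, either as a single column
or as ``timestep,label`` pairs, with the alphabet {0, 1, 2} mapping to
{NON_FALL, PRE_FALL, FALL}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .labels import ClassLabel, validate_labels


class ParseError(ValueError):
    """A raw trial or annotation file is malformed."""


class MetadataError(ValueError):
    """A filename does not follow the SisFall naming convention."""


class AlignmentError(ValueError):
    """Annotation length disagrees with the trial length."""


class FormatError(ValueError):
    """A stored block dataset container is corrupt or unreadable."""


# --------------------------------------------------------------------------
# ADC scaling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorScale:
    """Linear ADC-to-physical conversion for one tri-axial sensor.

    ``factor = 2 * range / 2**bits`` (units per count), the conversion for a
    symmetric full-scale range digitised at the given resolution.
    """

    range_units: float
    bits: int

    @property
    def factor(self) -> float:
        if self.range_units <= 0 or self.bits <= 0:
            raise ValueError("sensor range and bit depth must be positive")
        return 2.0 * self.range_units / float(2 ** self.bits)


@dataclass(frozen=True)
class ChannelScaleConfig:
    """Per-sensor scales for the 9-channel SisFall layout.

    Defaults are the published SisFall device constants: ADXL345 (+-16 g,
    13 bit), ITG3200 (+-2000 deg/s, 16 bit), MMA8451Q (+-8 g, 14 bit).
    """

    accel1: SensorScale = field(default_factory=lambda: SensorScale(16.0, 13))
    gyro: SensorScale = field(default_factory=lambda: SensorScale(2000.0, 16))
    accel2: SensorScale = field(default_factory=lambda: SensorScale(8.0, 14))

    def factors(self, n_channels: int) -> np.ndarray:
        """Per-channel multiplicative factors for 9 or 6 channel layouts."""
        f1, fg, f2 = self.accel1.factor, self.gyro.factor, self.accel2.factor
        if n_channels == 9:
            per_sensor = [f1, fg, f2]
        elif n_channels == 6:
            per_sensor = [f1, fg]
        else:
            raise ParseError(
                f"expected 6 or 9 channels per row, got {n_channels}"
            )
        return np.repeat(np.asarray(per_sensor, dtype=np.float64), 3)


# --------------------------------------------------------------------------
# Trial containers
# --------------------------------------------------------------------------

@dataclass
class RawTrial:
    """One recording: T x C physical-unit samples plus subject metadata."""

    subject_id: str
    subject_group: str          # "young" | "elderly"
    activity_code: str
    activity_class: str         # "ADL" | "FALL"
    trial_index: int
    samples: np.ndarray         # (T, C) float64
    sample_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.shape[0] < 1:
            raise ValueError("a trial must contain at least one sample")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def trial_id(self) -> str:
        return f"{self.activity_code}_{self.subject_id}_R{self.trial_index:02d}"


@dataclass
class AnnotatedTrial:
    """A trial plus one class label per timestep."""

    trial: RawTrial
    labels: np.ndarray          # (T,) int8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (self.trial.n_samples,):
            raise AlignmentError(
                f"{self.labels.shape[0]} labels for "
                f"{self.trial.n_samples} samples"
            )
        validate_labels(self.labels)

    def with_samples(self, samples: np.ndarray) -> "AnnotatedTrial":
        """Same labels/metadata with a replaced sample matrix."""
        return AnnotatedTrial(replace(self.trial, samples=samples), self.labels)


# Channel selection: first accelerometer + gyroscope (the 6 training axes);
# the second accelerometer is retained in RawTrial but dropped here.
TRAIN_CHANNELS = np.arange(6)


def select_channels(trial: RawTrial, channels=TRAIN_CHANNELS) -> RawTrial:
    channels = np.asarray(channels)
    if channels.max() >= trial.n_channels:
        raise ValueError(
            f"channel index {channels.max()} out of range for "
            f"{trial.n_channels}-channel trial"
        )
    return replace(trial, samples=trial.samples[:, channels])


# --------------------------------------------------------------------------
# File readers
# --------------------------------------------------------------------------

_FILENAME_RE = re.compile(
    r"^(?P<activity>[A-Za-z]\d+)_(?P<subject>[A-Za-z]+\d+)_R(?P<trial>\d+)$"
)


def parse_trial_filename(path: Path | str) -> dict:
    """Extract activity/subject/trial metadata from a SisFall filename."""
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if m is None:
        raise MetadataError(
            f"filename {stem!r} does not match <activity>_<subject>_R<trial>"
        )
    activity = m.group("activity").upper()
    subject = m.group("subject").upper()
    return {
        "activity_code": activity,
        "activity_class": "FALL" if activity.startswith("F") else "ADL",
        "subject_id": subject,
        # SisFall convention: SA = young adult, SE = elderly
        "subject_group": "elderly" if subject.startswith("SE") else "young",
        "trial_index": int(m.group("trial")),
    }


def _split_row(line: str) -> list[str]:
    return [f for f in re.split(r"[,;]", line.strip()) if f.strip()]


def read_raw_trial(
    path: Path | str,
    scale: ChannelScaleConfig | None = None,
    sample_rate_hz: float = 200.0,
) -> RawTrial:
    """Parse one SisFall-style trial file into physical units.

    Raises ``ParseError`` (naming the line) for malformed rows and
    ``MetadataError`` for an unrecognised filename.
    """
    scale = scale or ChannelScaleConfig()
    path = Path(path)
    meta = parse_trial_filename(path)

    rows: list[list[int]] = []
    n_fields: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_row(line)
            if n_fields is None:
                n_fields = len(fields)
                factors = scale.factors(n_fields)  # validates scale early
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path.name}: line {lineno} has {len(fields)} fields, "
                    f"expected {n_fields}"
                )
            try:
                rows.append([int(f) for f in fields])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}: line {lineno}: non-integer field ({exc})"
                ) from None
    if not rows:
        raise ParseError(f"{path.name}: file contains no samples")

    counts = np.asarray(rows, dtype=np.float64)
    samples = counts * factors[np.newaxis, :]
    return RawTrial(samples=samples, sample_rate_hz=sample_rate_hz, **meta)


def read_annotations(path: Path | str, trial: RawTrial) -> AnnotatedTrial:
    """Read per-sample labels and align them 1:1 with a trial.

    Accepts a single label column or ``timestep,label`` pairs.
    """
    path = Path(path)
    labels: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_row(line)
            if len(fields) == 1:
                value = fields[0]
            elif len(fields) == 2:
                value = fields[1]
            else:
                raise ParseError(
                    f"{path.name}: line {lineno} has {len(fields)} fields, "
                    "expected 1 (label) or 2 (timestep,label)"
                )
            try:
                labels.append(int(value))
            except ValueError:
                raise ParseError(
                    f"{path.name}: line {lineno}: non-integer label {value!r}"
                ) from None

    if len(labels) != trial.n_samples:
        raise AlignmentError(
            f"{path.name}: {len(labels)} labels for trial "
            f"{trial.trial_id} with {trial.n_samples} samples"
        )
    validate_labels(labels)
    return AnnotatedTrial(trial, np.asarray(labels, dtype=np.int8))


# --------------------------------------------------------------------------
# Block dataset container
# --------------------------------------------------------------------------

@dataclass
class BlockDataset:
    """Segmented, labeled windows with subject provenance.

    ``X`` holds the stacked block sample matrices, ``y`` the block labels.
    Provenance arrays travel with the data so subject-wise splits can be
    enforced at any point downstream.
    """

    X: np.ndarray               # (n, W, C)
    y: np.ndarray               # (n,) int8
    subjects: np.ndarray        # (n,) str
    groups: np.ndarray          # (n,) str: "young" | "elderly"
    trial_ids: np.ndarray       # (n,) str
    starts: np.ndarray          # (n,) int64, 0-based window starts

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        n = len(self.y)
        if not (
            self.X.shape[0] == n
            == len(self.subjects) == len(self.groups)
            == len(self.trial_ids) == len(self.starts)
        ):
            raise ValueError("block dataset arrays have inconsistent lengths")
        validate_labels(self.y)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "BlockDataset":
        idx = np.asarray(idx)
        return BlockDataset(
            self.X[idx], self.y[idx], self.subjects[idx],
            self.groups[idx], self.trial_ids[idx], self.starts[idx],
        )

    def subject_set(self) -> set[str]:
        return set(self.subjects.tolist())

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=len(ClassLabel))

    def equals(self, other: "BlockDataset") -> bool:
        return (
            self.X.shape == other.X.shape
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.y, other.y)
            and all(
                np.array_equal(a.astype(str), b.astype(str))
                for a, b in [
                    (self.subjects, other.subjects),
                    (self.groups, other.groups),
                    (self.trial_ids, other.trial_ids),
                ]
            )
            and np.array_equal(self.starts, other.starts)
        )


_STR = h5py.string_dtype(encoding="utf-8")


def save_block_dataset(dataset: BlockDataset, path: Path | str) -> None:
    """Persist a block dataset to an HDF5 container (lossless round-trip)."""
    if len(dataset) == 0:
        raise ValueError("refusing to save an empty block dataset")
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=dataset.X)
        f.create_dataset("y", data=dataset.y)
        for name in ("subjects", "groups", "trial_ids"):
            f.create_dataset(
                name, data=getattr(dataset, name).astype(str).tolist(),
                dtype=_STR,
            )
        f.create_dataset("starts", data=dataset.starts)


def load_block_dataset(path: Path | str) -> BlockDataset:
    try:
        with h5py.File(path, "r") as f:
            def _str(name):
                return np.asarray(
                    [s.decode() if isinstance(s, bytes) else str(s)
                     for s in f[name][()]],
                    dtype=object,
                )
            return BlockDataset(
                X=f["X"][()], y=f["y"][()],
                subjects=_str("subjects"), groups=_str("groups"),
                trial_ids=_str("trial_ids"), starts=f["starts"][()],
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read block dataset {path}: {exc}") from exc
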