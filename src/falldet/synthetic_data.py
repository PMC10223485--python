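"""Synthetic multi-subject IMU trial generator.

Emulates the statistical structure of waist-worn 200 Hz recordings that the
pipeline assumes, so the whole stack is testable without downloading real
data: gravity-dominated quasi-periodic daily-living activity, a hazardous
transition phase with rising tilt and elevated jerk (pre-fall), and for
actual falls a free-fall dip, a sharp impact peak, and post-impact rest.

The signal model is phenomenological — gravity projection plus band-limited
gait oscillation plus event templates plus Gaussian noise — not a
biomechanical simulation.  Its job is to give every class a learnable,
subject-varying signature with realistic imbalance (non-fall blocks
dominate), not to match any real dataset's per-activity statistics.

Three trial kinds mirror the annotation taxonomy: plain daily activity
(labels all NON_FALL), a near-fall in which the hazard resolves without
impact (NON_FALL -> PRE_FALL -> NON_FALL), and a fall with impact
(NON_FALL -> PRE_FALL -> FALL, with the person then at rest on the ground,
still labeled FALL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .io_formats import (
    AnnotatedTrial,
    ChannelScaleConfig,
    RawTrial,
)
from .labels import ClassLabel

TRIAL_KINDS = ("ADL", "NEAR_FALL", "FALL_WITH_IMPACT")

#: SisFall-style activity codes the writer uses for each trial kind.
KIND_CODES = {"ADL": "D01", "NEAR_FALL": "F01", "FALL_WITH_IMPACT": "F02"}


@dataclass
class SyntheticConfig:
    """Study conditions for the generated cohort.

    ``fall_duration_s`` (0.8 s) is the descent-plus-impact span of a fall;
    after it the subject lies still for ``post_fall_rest_s``, a period that
    keeps the FALL label.  ``hazard_duration_s`` is the length of the
    pre-fall state in near-fall trials (a stumble plus recovery takes a few
    seconds); the pre-impact hazard of an actual fall is much shorter
    (``prefall_duration_s``).
    """

    n_young: int = 4
    n_elderly: int = 2
    trials_per_subject: int = 36
    sample_rate_hz: float = 200.0
    adl_amplitude_g: float = 0.25
    fall_peak_g: float = 3.0
    prefall_duration_s: float = 0.3
    hazard_duration_s: float = 3.0
    fall_duration_s: float = 0.8
    post_fall_rest_s: float = 2.5
    adl_duration_s: float = 8.0
    noise_std: float = 0.02
    gyro_scale_dps: float = 40.0
    difficulty: str = "easy"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_young, self.n_elderly, self.trials_per_subject) < 1:
            raise ValueError("subject and trial counts must be >= 1")
        for name in ("prefall_duration_s", "hazard_duration_s",
                     "fall_duration_s", "adl_duration_s", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fall_peak_g <= self.adl_amplitude_g:
            raise ValueError("fall_peak_g must exceed adl_amplitude_g")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")

    @classmethod
    def easy(cls, **overrides) -> "SyntheticConfig":
        """Well-separated preset: training is expected to succeed."""
        return cls(**{"difficulty": "easy", **overrides})

    @classmethod
    def hard(cls, **overrides) -> "SyntheticConfig":
        """Overlapping-amplitude preset exercising imbalance handling."""
        defaults = dict(
            difficulty="hard", adl_amplitude_g=0.5, fall_peak_g=1.2,
            noise_std=0.08,
        )
        return cls(**{**defaults, **overrides})


@dataclass
class SubjectProfile:
    """Per-subject gait parameters so subject-wise splits are meaningful."""

    subject_id: str
    group: str                  # "young" | "elderly"
    gait_freq_hz: float
    amp_scale: float
    lean_rad: float


def _make_profile(subject_id: str, group: str,
                  rng: np.random.Generator) -> SubjectProfile:
    lo, hi = (1.7, 2.2) if group == "young" else (1.3, 1.7)
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        gait_freq_hz=rng.uniform(lo, hi),
        amp_scale=rng.uniform(0.8, 1.2),
        lean_rad=rng.uniform(-0.12, 0.12),
    )


# --------------------------------------------------------------------------
# Segment builders (each returns (n, 3) accel in g and (n, 3) gyro in deg/s)
# --------------------------------------------------------------------------

def _adl_segment(n: int, cfg: SyntheticConfig, prof: SubjectProfile,
                 rng: np.random.Generator, t0: float = 0.0):
    fs = cfg.sample_rate_hz
    t = t0 + np.arange(n) / fs
    amp = cfg.adl_amplitude_g * prof.amp_scale
    w = 2 * np.pi * prof.gait_freq_hz
    phase = rng.uniform(0, 2 * np.pi)
    acc = np.empty((n, 3))
    # gravity along +z for an upright subject, slightly leaned
    acc[:, 0] = np.sin(prof.lean_rad) + amp * np.sin(w * t + phase)
    acc[:, 1] = 0.4 * amp * np.sin(2 * w * t + phase / 2)
    acc[:, 2] = np.cos(prof.lean_rad) + 0.6 * amp * np.sin(2 * w * t + phase)
    gyro = np.empty((n, 3))
    g_amp = cfg.gyro_scale_dps * prof.amp_scale
    gyro[:, 0] = g_amp * np.sin(w * t + phase + 0.3)
    gyro[:, 1] = 0.5 * g_amp * np.sin(w * t + phase + 1.1)
    gyro[:, 2] = 0.3 * g_amp * np.sin(2 * w * t + phase)
    return acc, gyro


def _hazard_segment(n: int, cfg: SyntheticConfig, prof: SubjectProfile,
                    rng: np.random.Generator):
    """Pre-fall: rising tilt plus elevated jerk (fast wobble, gyro surge)."""
    fs = cfg.sample_rate_hz
    t = np.arange(n) / fs
    ramp = np.linspace(0.0, 1.0, n)
    tilt = prof.lean_rad + ramp * np.deg2rad(40.0)
    wob_f = rng.uniform(6.0, 9.0)
    wobble = 2.5 * cfg.adl_amplitude_g * ramp * np.sin(2 * np.pi * wob_f * t)
    acc = np.empty((n, 3))
    acc[:, 0] = np.sin(tilt) + wobble
    acc[:, 1] = 0.6 * wobble * np.sin(2 * np.pi * wob_f * t + 0.7)
    acc[:, 2] = np.cos(tilt) + 0.5 * wobble
    gyro = np.empty((n, 3))
    surge = (2.0 + 3.0 * ramp) * cfg.gyro_scale_dps
    gyro[:, 0] = surge * np.sin(2 * np.pi * wob_f * t)
    gyro[:, 1] = 0.8 * surge * np.sin(2 * np.pi * wob_f * t + 0.9)
    gyro[:, 2] = 0.4 * surge * np.sin(2 * np.pi * wob_f * t + 1.7)
    return acc, gyro


def _fall_segment(n: int, cfg: SyntheticConfig, prof: SubjectProfile,
                  rng: np.random.Generator):
    """Free-fall dip, impact peak of ~fall_peak_g, then ringing decay."""
    fs = cfg.sample_rate_hz
    n_dip = max(int(0.25 * fs), 2)
    n_peak = max(int(0.06 * fs), 2)
    n_dip = min(n_dip, n - n_peak - 1)
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    # free fall: total acceleration norm collapses toward zero
    dip = np.linspace(1.0, 0.15, n_dip)
    acc[:n_dip, 2] = dip
    # impact: half-sine spike along a random direction, peak norm fall_peak_g
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    spike = cfg.fall_peak_g * np.sin(np.linspace(0, np.pi, n_peak))
    acc[n_dip:n_dip + n_peak, :] = spike[:, None] * direction[None, :]
    # rotation rate surges during descent and impact
    gyro[:n_dip + n_peak, :] = rng.normal(
        0.0, 6.0 * cfg.gyro_scale_dps, size=(n_dip + n_peak, 3)
    )
    # ringing decay after impact, settling toward lying orientation
    n_rest = n - n_dip - n_peak
    if n_rest > 0:
        t = np.arange(n_rest) / fs
        ring = np.exp(-8.0 * t) * 0.8 * cfg.fall_peak_g * np.sin(2 * np.pi * 12.0 * t)
        acc[n_dip + n_peak:, 0] = 1.0 + ring          # gravity now along x: lying down
        acc[n_dip + n_peak:, 2] = 0.1 + 0.3 * ring
        gyro[n_dip + n_peak:, :] = (
            np.exp(-8.0 * t)[:, None]
            * rng.normal(0.0, 2.0 * cfg.gyro_scale_dps, size=(n_rest, 3))
        )
    return acc, gyro


def _rest_segment(n: int, cfg: SyntheticConfig):
    """Post-impact rest: lying still, gravity on the x axis."""
    acc = np.zeros((n, 3))
    acc[:, 0] = 1.0
    return acc, np.zeros((n, 3))


# --------------------------------------------------------------------------
# Trial and dataset generation
# --------------------------------------------------------------------------

def _assemble(parts, labels, cfg: SyntheticConfig, prof: SubjectProfile,
              kind: str, trial_index: int, rng: np.random.Generator
              ) -> AnnotatedTrial:
    acc = np.concatenate([p[0] for p in parts], axis=0)
    gyro = np.concatenate([p[1] for p in parts], axis=0)
    n = acc.shape[0]
    acc = acc + rng.normal(0.0, cfg.noise_std, size=acc.shape)
    gyro = gyro + rng.normal(0.0, cfg.noise_std * cfg.gyro_scale_dps * 2,
                             size=gyro.shape)
    # second accelerometer: same physics, different sensor noise floor
    acc2 = acc + rng.normal(0.0, cfg.noise_std * 1.5, size=acc.shape)
    samples = np.concatenate([acc, gyro, acc2], axis=1)
    trial = RawTrial(
        subject_id=prof.subject_id,
        subject_group=prof.group,
        activity_code=KIND_CODES[kind],
        activity_class="ADL" if kind == "ADL" else "FALL",
        trial_index=trial_index,
        samples=samples,
        sample_rate_hz=cfg.sample_rate_hz,
    )
    return AnnotatedTrial(trial, np.concatenate(labels).astype(np.int8))


def generate_trial(
    kind: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    profile: SubjectProfile | None = None,
    trial_index: int = 1,
) -> AnnotatedTrial:
    """Generate one annotated trial of the given kind."""
    if kind not in TRIAL_KINDS:
        raise ValueError(f"unknown trial kind {kind!r}; one of {TRIAL_KINDS}")
    prof = profile or _make_profile("SA01", "young", rng)
    fs = cfg.sample_rate_hz
    n_adl = int(round(cfg.adl_duration_s * fs))

    def lab(value: ClassLabel, n: int) -> np.ndarray:
        return np.full(n, int(value), dtype=np.int8)

    if kind == "ADL":
        parts = [_adl_segment(n_adl, cfg, prof, rng)]
        labels = [lab(ClassLabel.NON_FALL, n_adl)]
    elif kind == "NEAR_FALL":
        n_pre = int(round(cfg.hazard_duration_s * fs))
        n_tail = int(round(0.5 * cfg.adl_duration_s * fs))
        parts = [
            _adl_segment(n_adl, cfg, prof, rng),
            _hazard_segment(n_pre, cfg, prof, rng),
            _adl_segment(n_tail, cfg, prof, rng, t0=n_adl / fs),
        ]
        labels = [
            lab(ClassLabel.NON_FALL, n_adl),
            lab(ClassLabel.PRE_FALL, n_pre),
            lab(ClassLabel.NON_FALL, n_tail),
        ]
    else:  # FALL_WITH_IMPACT
        n_pre = int(round(cfg.prefall_duration_s * fs))
        n_fall = int(round(cfg.fall_duration_s * fs))
        n_rest = int(round(cfg.post_fall_rest_s * fs))
        parts = [
            _adl_segment(n_adl, cfg, prof, rng),
            _hazard_segment(n_pre, cfg, prof, rng),
            _fall_segment(n_fall, cfg, prof, rng),
            _rest_segment(n_rest, cfg),
        ]
        labels = [
            lab(ClassLabel.NON_FALL, n_adl),
            lab(ClassLabel.PRE_FALL, n_pre),
            lab(ClassLabel.FALL, n_fall),
            lab(ClassLabel.FALL, n_rest),   # lying on the ground: still a fall state
        ]
    return _assemble(parts, labels, cfg, prof, kind, trial_index, rng)


@dataclass
class SyntheticDataset:
    trials: list[AnnotatedTrial]
    profiles: list[SubjectProfile] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles]


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full multi-subject cohort.

    Trial kinds cycle ADL -> NEAR_FALL -> FALL_WITH_IMPACT per subject, so a
    third of trials are plain daily activity and non-fall timesteps dominate
    overall (every trial starts with a daily-activity run-in).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    profiles = [
        _make_profile(f"SA{i + 1:02d}", "young", rng) for i in range(cfg.n_young)
    ] + [
        _make_profile(f"SE{i + 1:02d}", "elderly", rng) for i in range(cfg.n_elderly)
    ]
    trials: list[AnnotatedTrial] = []
    for prof in profiles:
        per_code_counter: dict[str, int] = {}
        for j in range(cfg.trials_per_subject):
            kind = TRIAL_KINDS[j % len(TRIAL_KINDS)]
            code = KIND_CODES[kind]
            per_code_counter[code] = per_code_counter.get(code, 0) + 1
            trials.append(generate_trial(
                kind, cfg, rng, profile=prof,
                trial_index=per_code_counter[code],
            ))
    return SyntheticDataset(trials=trials, profiles=profiles)


# --------------------------------------------------------------------------
# SisFall-dialect writer (exercises the real reader path)
# --------------------------------------------------------------------------

def write_sisfall_dataset(
    dataset: SyntheticDataset | Iterable[AnnotatedTrial],
    raw_dir: Path | str,
    annot_dir: Path | str,
    scale: ChannelScaleConfig | None = None,
) -> list[str]:
    """Emit trials as SisFall-style ADC-count text files plus annotations.

    Physical values are quantised to integer counts with the same per-sensor
    scale factors the reader applies, so a write/read round trip differs only
    by quantisation.  Returns the list of trial stems written.
    """
    scale = scale or ChannelScaleConfig()
    raw_dir, annot_dir = Path(raw_dir), Path(annot_dir)
    raw_dir.mkdir(parents=True, exist_ok=True)
    annot_dir.mkdir(parents=True, exist_ok=True)
    trials = dataset.trials if isinstance(dataset, SyntheticDataset) else list(dataset)
    stems = []
    for at in trials:
        trial = at.trial
        factors = scale.factors(trial.n_channels)
        counts = np.rint(trial.samples / factors[np.newaxis, :]).astype(np.int64)
        stem = trial.trial_id
        with open(raw_dir / f"{stem}.txt", "w") as fh:
            for row in counts:
                fh.write(",".join(str(int(v)) for v in row) + ";\n")
        with open(annot_dir / f"{stem}.txt", "w") as fh:
            fh.write("\n".join(str(int(v)) for v in at.labels) + "\n")
        stems.append(stem)
    return stems
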