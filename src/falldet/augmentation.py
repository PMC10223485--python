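"""Label-preserving online augmentation for IMU blocks.

Three transforms, each leaving the block label untouched:

* **rotation** — one random 3-D rotation (uniform axis, angle uniform in a
  configured range) applied to every timestep and to every xyz triplet of
  the block.  Accelerometer and gyroscope triplets get the same matrix: a
  physical re-orientation of the worn device rotates both sensors
  identically, which is the effect being simulated.
* **scaling** — one scalar per block, drawn from N(1, 0.1) by default.
* **jitter** — i.i.d. Gaussian noise (sigma 0.01 by default) added
  element-wise, simulating sensor noise.

Batches are augmented online (during batch assembly, nothing written to
disk): half of each batch is replaced by a transformed copy, each selected
block receiving exactly one transform drawn from the configured
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .preprocessing import Block

_TRANSFORM_NAMES = ("rotation", "scaling", "jitter")


@dataclass
class AugmentationConfig:
    rotation_angle_range: tuple[float, float] = (-np.pi, np.pi)
    scale_mean: float = 1.0
    scale_std: float = 0.1
    jitter_std: float = 0.01
    transform_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    per_channel_scaling: bool = False
    augmented_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.transform_probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("transform_probs must be 3 non-negative reals summing to 1")
        if self.scale_std < 0 or self.jitter_std < 0:
            raise ValueError("scale_std and jitter_std must be non-negative")
        if not 0.0 <= self.augmented_fraction <= 1.0:
            raise ValueError("augmented_fraction must lie in [0, 1]")


def random_rotation_matrix(rng: np.random.Generator, angle_range) -> np.ndarray:
    """Rotation about a uniformly random axis by a uniform random angle.

    Rodrigues' formula; the axis is drawn uniformly on the unit sphere.
    """
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    while norm < 1e-12:  # pragma: no cover - probability zero
        axis = rng.normal(size=3)
        norm = np.linalg.norm(axis)
    axis = axis / norm
    theta = rng.uniform(*angle_range)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


# --------------------------------------------------------------------------
# Array-level transforms (the training loop operates on stacked arrays)
# --------------------------------------------------------------------------

def rotate_samples(x: np.ndarray, rng: np.random.Generator,
                   cfg: AugmentationConfig) -> np.ndarray:
    """Apply one shared random rotation to every xyz triplet of a (W, C) window."""
    W, C = x.shape
    if C % 3 != 0:
        raise ValueError(f"channel count {C} is not a multiple of 3")
    R = random_rotation_matrix(rng, cfg.rotation_angle_range)
    out = x.reshape(W, C // 3, 3) @ R.T
    return out.reshape(W, C)


def scale_samples(x: np.ndarray, rng: np.random.Generator,
                  cfg: AugmentationConfig) -> np.ndarray:
    """Multiply the window by one normal-distributed scalar (or one per channel)."""
    if cfg.per_channel_scaling:
        factors = rng.normal(cfg.scale_mean, cfg.scale_std, size=x.shape[1])
        return x * factors[np.newaxis, :]
    return x * rng.normal(cfg.scale_mean, cfg.scale_std)


def jitter_samples(x: np.ndarray, rng: np.random.Generator,
                   cfg: AugmentationConfig) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise element-wise."""
    return x + rng.normal(0.0, cfg.jitter_std, size=x.shape)


_ARRAY_TRANSFORMS = (rotate_samples, scale_samples, jitter_samples)


# --------------------------------------------------------------------------
# Block-level API
# --------------------------------------------------------------------------

def _transformed_block(block: Block, samples: np.ndarray) -> Block:
    return _dc_replace(block, samples=samples)


def rotate_block(block: Block, rng: np.random.Generator,
                 cfg: AugmentationConfig) -> Block:
    return _transformed_block(block, rotate_samples(block.samples, rng, cfg))


def scale_block(block: Block, rng: np.random.Generator,
                cfg: AugmentationConfig) -> Block:
    return _transformed_block(block, scale_samples(block.samples, rng, cfg))


def jitter_block(block: Block, rng: np.random.Generator,
                 cfg: AugmentationConfig) -> Block:
    return _transformed_block(block, jitter_samples(block.samples, rng, cfg))


def augment_arrays(X: np.ndarray, rng: np.random.Generator,
                   cfg: AugmentationConfig) -> np.ndarray:
    """Online half-batch augmentation on a stacked (n, W, C) batch.

    Exactly ``floor(augmented_fraction * n)`` windows, chosen uniformly
    without replacement, are replaced by a transformed copy; each receives
    one transform drawn from ``transform_probs``.  Order, batch size and
    labels (held elsewhere) are untouched.
    """
    n = X.shape[0]
    if n == 0:
        raise ValueError("batch must be non-empty")
    k = int(np.floor(cfg.augmented_fraction * n))
    out = X.copy()
    if k == 0:
        return out
    chosen = rng.choice(n, size=k, replace=False)
    kinds = rng.choice(3, size=k, p=np.asarray(cfg.transform_probs, dtype=float))
    for idx, kind in zip(chosen, kinds):
        out[idx] = _ARRAY_TRANSFORMS[kind](X[idx], rng, cfg)
    return out


def augment_batch(batch: list[Block], rng: np.random.Generator,
                  cfg: AugmentationConfig) -> list[Block]:
    """Block-object counterpart of :func:`augment_arrays`."""
    if not batch:
        raise ValueError("batch must be non-empty")
    X = np.stack([b.samples for b in batch])
    out = augment_arrays(X, rng, cfg)
    return [
        b if np.array_equal(out[i], X[i]) else _transformed_block(b, out[i])
        for i, b in enumerate(batch)
    ]
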