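"""Subject-wise splitting, weighted one-vs-rest binary cross-entropy, and
the training loop with online augmentation.

The evaluation protocol is subject-wise: a set of held-out subjects (by
default four young and two elderly, drawn deterministically from the
declared groups) forms the test set, and the remaining subjects' blocks are
split 80/20 into train/validation, stratified by block label.  No subject
ever appears on both sides of the test boundary, which is what makes the
reported metrics an estimate of performance on unseen people.

Each ensemble sub-model is supervised as a one-vs-rest binary task: the
loss is the sum over classes of class-weighted binary cross-entropy between
the sub-model's sigmoid score and the one-hot target.  Class weights
default to inverse frequency, normalized so the smallest weight is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import nn
from .architecture import ClassEnsembleNetwork, fuse_batch
from .augmentation import AugmentationConfig, augment_arrays
from .io_formats import BlockDataset
from .labels import ClassLabel


class ConfigurationError(ValueError):
    """A requested split or weighting cannot be realised on this dataset."""


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during training."""


@dataclass
class SplitSpec:
    """Which subjects are held out, and how the rest are divided."""

    test_subjects: tuple[str, ...] | None = None
    n_test_young: int = 4
    n_test_elderly: int = 2
    train_val_ratio: float = 0.8
    split_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_val_ratio < 1.0:
            raise ValueError("train_val_ratio must lie in (0, 1)")


@dataclass
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 200
    learning_rate: float = 0.0005
    optimizer: str = "adam"
    class_weights: tuple[float, ...] | str = "auto"
    early_stop_patience: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


# --------------------------------------------------------------------------
# Splits
# --------------------------------------------------------------------------

def choose_test_subjects(dataset: BlockDataset, spec: SplitSpec) -> tuple[str, ...]:
    """Resolve the held-out subject list, drawing from groups if needed."""
    if spec.test_subjects is not None:
        missing = set(spec.test_subjects) - dataset.subject_set()
        if missing:
            raise ConfigurationError(
                f"test subjects absent from dataset: {sorted(missing)}"
            )
        return tuple(spec.test_subjects)
    roster: dict[str, str] = {}
    for subj, grp in zip(dataset.subjects, dataset.groups):
        roster[str(subj)] = str(grp)
    young = sorted(s for s, g in roster.items() if g == "young")
    elderly = sorted(s for s, g in roster.items() if g == "elderly")
    if len(young) < spec.n_test_young or len(elderly) < spec.n_test_elderly:
        raise ConfigurationError(
            f"roster has {len(young)} young / {len(elderly)} elderly subjects; "
            f"cannot hold out {spec.n_test_young}+{spec.n_test_elderly}"
        )
    rng = np.random.default_rng(spec.split_seed)
    chosen = list(rng.choice(young, size=spec.n_test_young, replace=False))
    chosen += list(rng.choice(elderly, size=spec.n_test_elderly, replace=False))
    return tuple(str(s) for s in chosen)


def make_splits(
    dataset: BlockDataset, spec: SplitSpec
) -> tuple[BlockDataset, BlockDataset, BlockDataset]:
    """Subject-wise test split, then stratified 80/20 train/validation.

    Returns ``(train, val, test)``.  Test blocks come exclusively from the
    held-out subjects; the remaining blocks are split by label-stratified
    sampling so per-class proportions agree to within one block.
    """
    if len(dataset.subject_set()) < 3:
        raise ConfigurationError("need at least 3 subjects for a subject-wise split")
    test_subjects = set(choose_test_subjects(dataset, spec))
    is_test = np.asarray([str(s) in test_subjects for s in dataset.subjects])
    test = dataset.subset(np.nonzero(is_test)[0])
    rest_idx = np.nonzero(~is_test)[0]
    if len(rest_idx) == 0:
        raise ConfigurationError("no blocks left outside the test subjects")
    rest_labels = dataset.y[rest_idx]
    train_idx, val_idx = train_test_split(
        rest_idx,
        train_size=spec.train_val_ratio,
        stratify=rest_labels,
        random_state=spec.split_seed,
        shuffle=True,
    )
    assert set(dataset.subjects[train_idx]) | set(dataset.subjects[val_idx]) <= (
        dataset.subject_set() - test_subjects
    ) or not test_subjects
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(val_idx)), test


# --------------------------------------------------------------------------
# Loss and class weights
# --------------------------------------------------------------------------

def class_weights_auto(train: BlockDataset, n_classes: int = 3) -> np.ndarray:
    """Inverse-frequency weights ``N / (n_classes * N_c)``, min-normalized to 1."""
    counts = np.bincount(train.y, minlength=n_classes)
    if (counts == 0).any():
        empty = [ClassLabel(int(i)).name for i in np.nonzero(counts == 0)[0]]
        raise ConfigurationError(
            f"class(es) {empty} absent from the training set; "
            "pass explicit class weights"
        )
    w = counts.sum() / (n_classes * counts.astype(float))
    return w / w.min()


_EPS = 1e-7


def weighted_bce_loss(
    scores: np.ndarray,
    target: int | ClassLabel | np.ndarray,
    weights: Sequence[float] | np.ndarray,
) -> float:
    """Sum over classes of weighted one-vs-rest binary cross-entropy.

    ``scores`` is a single class-score vector or an (n, C) batch of them;
    ``target`` the true class index (or vector of indices).  Scores are
    clipped to ``[1e-7, 1 - 1e-7]`` before the logs.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    t = np.atleast_1d(np.asarray(target, dtype=int))
    w = np.asarray(weights, dtype=float)
    if s.shape[1] != w.shape[0]:
        raise ValueError("weights length must match the number of classes")
    onehot = np.eye(s.shape[1])[t]
    p = np.clip(s, _EPS, 1.0 - _EPS)
    per_class = -(onehot * np.log(p) + (1.0 - onehot) * np.log1p(-p))
    return float((per_class * w).sum(axis=1).mean())


def _bce_from_logits(logits: np.ndarray, targets: np.ndarray,
                     weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable loss and gradient w.r.t. the logits."""
    onehot = np.eye(logits.shape[1])[targets]
    # softplus-based BCE: t*softplus(-z) + (1-t)*softplus(z)
    sp_pos = np.logaddexp(0.0, logits)
    sp_neg = np.logaddexp(0.0, -logits)
    per_class = onehot * sp_neg + (1.0 - onehot) * sp_pos
    loss = float((per_class * weights).sum(axis=1).mean())
    dlogits = weights * (nn.sigmoid(logits) - onehot) / logits.shape[0]
    return loss, dlogits


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

@dataclass
class TrainingResult:
    model: ClassEnsembleNetwork
    history: pd.DataFrame
    best_epoch: int
    class_weights: np.ndarray


def _per_class_sensitivity(pred: np.ndarray, truth: np.ndarray,
                           n_classes: int) -> np.ndarray:
    out = np.full(n_classes, np.nan)
    for c in range(n_classes):
        mask = truth == c
        if mask.any():
            out[c] = float((pred[mask] == c).mean())
    return out


def _forward_in_chunks(model: ClassEnsembleNetwork, X: np.ndarray,
                       chunk: int = 512) -> np.ndarray:
    return np.concatenate([
        model.forward(X[i:i + chunk], training=False)
        for i in range(0, len(X), chunk)
    ])


def train(
    model: ClassEnsembleNetwork,
    train_ds: BlockDataset,
    val_ds: BlockDataset,
    cfg: TrainConfig,
    aug_cfg: AugmentationConfig | None = None,
) -> TrainingResult:
    """Train the ensemble with Adam, online augmentation, and best-val
    checkpointing.

    Every training batch passes through the online augmentation step (when
    ``aug_cfg`` is given) before the forward/backward pass.  The weights
    restored at the end are those of the epoch with the lowest validation
    loss.  All randomness (shuffling, augmentation, dropout) is driven by
    ``cfg.rng_seed``.
    """
    n_classes = model.spec.n_classes
    if cfg.class_weights == "auto":
        weights = class_weights_auto(train_ds, n_classes)
    else:
        weights = np.asarray(cfg.class_weights, dtype=float)
        if weights.shape != (n_classes,):
            raise ConfigurationError("class_weights length must equal n_classes")
    rng = np.random.default_rng(cfg.rng_seed)
    model.seed_dropout(rng)
    opt = nn.Adam(model.layers, lr=cfg.learning_rate)

    X, y = train_ds.X, train_ds.y.astype(int)
    Xv, yv = val_ds.X, val_ds.y.astype(int)
    history: list[dict] = []
    best_val = np.inf
    best_epoch = -1
    best_weights = model.get_weights()
    since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = X[idx]
            if aug_cfg is not None and aug_cfg.augmented_fraction > 0:
                xb = augment_arrays(xb, rng, aug_cfg)
            opt.zero_grad()
            logits = model.forward(xb, training=True)
            loss, dlogits = _bce_from_logits(logits, y[idx], weights)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1

        val_logits = _forward_in_chunks(model, Xv)
        val_loss, _ = _bce_from_logits(val_logits, yv, weights)
        val_pred = fuse_batch(nn.sigmoid(val_logits))
        sens = _per_class_sensitivity(val_pred, yv, n_classes)
        history.append({
            "epoch": epoch + 1,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
            **{f"val_sens_{ClassLabel(c).name.lower()}": sens[c]
               for c in range(min(n_classes, len(ClassLabel)))},
        })
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch + 1
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if (cfg.early_stop_patience is not None
                    and since_best >= cfg.early_stop_patience):
                break

    model.set_weights(best_weights)
    return TrainingResult(
        model=model,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
        class_weights=weights,
    )


def train_replicates(
    build_model,
    train_ds: BlockDataset,
    val_ds: BlockDataset,
    cfg: TrainConfig,
    aug_cfg: AugmentationConfig | None = None,
    seeds: Sequence[int] = (0, 1, 2),
) -> list[TrainingResult]:
    """Replicate runs (default three seeds) for mean +- sd reporting.

    ``build_model(seed)`` must return a freshly initialised network.
    """
    results = []
    for seed in seeds:
        model = build_model(seed)
        run_cfg = TrainConfig(**{**cfg.__dict__, "rng_seed": int(seed)})
        results.append(train(model, train_ds, val_ds, run_cfg, aug_cfg))
    return results
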