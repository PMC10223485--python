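"""scikit-learn style estimator wrapping the class-based ensemble.

``FallEnsembleClassifier`` takes preprocessed blocks ``X`` of shape
``(n, block_width, channels)`` with integer class labels and handles
network construction, the internal train/validation split, online
augmentation, and argmax fusion.  It follows the scikit-learn estimator
contract (``get_params``/``set_params``, fitted attributes with a trailing
underscore, ``fit``/``predict``/``predict_proba``/``score``) so it composes
with sklearn model-selection utilities.

Note ``predict_proba`` returns the per-class one-vs-rest sigmoid scores:
each column is an independent binary probability, so rows do not sum to 1.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import nn
from .architecture import (
    ClassEnsembleNetwork,
    EnsembleSpec,
    fuse_batch,
)
from .augmentation import AugmentationConfig
from .io_formats import BlockDataset
from .labels import DEFAULT_TIE_BREAK
from .training import TrainConfig, train


def _as_dataset(X: np.ndarray, y: np.ndarray) -> BlockDataset:
    n = len(y)
    filler = np.asarray(["?"] * n, dtype=object)
    return BlockDataset(
        X=X, y=y, subjects=filler.copy(), groups=filler.copy(),
        trial_ids=filler.copy(), starts=np.zeros(n, dtype=np.int64),
    )


class FallEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Class-based CNN/RNN ensemble classifier for IMU blocks.

    Parameters mirror the architecture and training knobs; defaults are the
    configuration found best in tuning (three width-16 separable skipped
    convolution blocks with max pooling and swish, two width-16 LSTM layers,
    dropout 0.5, Adam at 5e-4 with batch 128).
    """

    def __init__(
        self,
        head_blocks: int = 3,
        head_widths: tuple[int, ...] = (16, 16, 16),
        conv_type: str = "separable",
        pooling: str = "max",
        activation: str = "swish",
        recurrent_layers: int = 2,
        recurrent_widths: tuple[int, ...] = (16, 16),
        recurrent_cell: str = "lstm",
        dropout_rate: float = 0.5,
        kernel_size: int = 5,
        batch_size: int = 128,
        max_epochs: int = 200,
        learning_rate: float = 0.0005,
        class_weights: tuple[float, ...] | str = "auto",
        early_stop_patience: int | None = None,
        augment: bool = True,
        augmented_fraction: float = 0.5,
        val_fraction: float = 0.2,
        random_state: int = 0,
    ) -> None:
        self.head_blocks = head_blocks
        self.head_widths = head_widths
        self.conv_type = conv_type
        self.pooling = pooling
        self.activation = activation
        self.recurrent_layers = recurrent_layers
        self.recurrent_widths = recurrent_widths
        self.recurrent_cell = recurrent_cell
        self.dropout_rate = dropout_rate
        self.kernel_size = kernel_size
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.class_weights = class_weights
        self.early_stop_patience = early_stop_patience
        self.augment = augment
        self.augmented_fraction = augmented_fraction
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _validate_X(self, X: np.ndarray, fitted: bool) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_blocks, block_width, channels); got shape {X.shape}"
            )
        if fitted and X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"X blocks of shape {X.shape[1:]} do not match the fitted "
                f"input shape {self.input_shape_}"
            )
        return X

    def _spec(self, input_shape: tuple[int, int], n_classes: int) -> EnsembleSpec:
        return EnsembleSpec(
            n_classes=n_classes,
            head_blocks=self.head_blocks,
            head_widths=tuple(self.head_widths),
            conv_type=self.conv_type,
            pooling=self.pooling,
            activation=self.activation,
            recurrent_layers=self.recurrent_layers,
            recurrent_widths=tuple(self.recurrent_widths),
            recurrent_cell=self.recurrent_cell,
            dropout_rate=self.dropout_rate,
            kernel_size=self.kernel_size,
            input_shape=input_shape,
        )

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y, val=None):
        """Fit on blocks ``X`` and labels ``y``.

        ``val`` may be a ``(X_val, y_val)`` pair; otherwise a stratified
        ``val_fraction`` of the training data is held out internally for
        checkpoint selection.  For a subject-wise protocol build the splits
        with :func:`falldet.training.make_splits` and pass ``val`` explicitly.
        """
        X = self._validate_X(X, fitted=False)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit")
        if not np.array_equal(self.classes_, np.arange(len(self.classes_))):
            raise ValueError("labels must be consecutive integers from 0")
        self.input_shape_ = X.shape[1:]

        if val is not None:
            X_tr, y_tr = X, y
            X_val, y_val = val
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val, dtype=int)
        else:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, test_size=self.val_fraction, stratify=y,
                random_state=self.random_state, shuffle=True,
            )

        spec = self._spec(tuple(self.input_shape_), len(self.classes_))
        self.network_ = ClassEnsembleNetwork(
            spec, np.random.default_rng(self.random_state)
        )
        self.n_params_ = self.network_.n_params
        cfg = TrainConfig(
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            learning_rate=self.learning_rate,
            class_weights=(self.class_weights if self.class_weights == "auto"
                           else tuple(self.class_weights)),
            early_stop_patience=self.early_stop_patience,
            rng_seed=self.random_state,
        )
        aug = (
            AugmentationConfig(augmented_fraction=self.augmented_fraction,
                               rng_seed=self.random_state)
            if self.augment else None
        )
        result = train(
            self.network_, _as_dataset(X_tr, y_tr), _as_dataset(X_val, y_val),
            cfg, aug,
        )
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.class_weights_ = result.class_weights
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X, fitted=True)
        return np.concatenate([
            self.network_.forward(X[i:i + 512], training=False)
            for i in range(0, len(X), 512)
        ])

    def predict_proba(self, X) -> np.ndarray:
        """Per-class one-vs-rest sigmoid scores (columns do not sum to 1)."""
        return nn.sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        scores = self.predict_proba(X)
        return fuse_batch(scores, DEFAULT_TIE_BREAK).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
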