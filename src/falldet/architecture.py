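"""The class-based ensemble architecture: a shared convolutional head
feeding one recurrent binary sub-model per event class, fused by argmax.

The head is a stack of *skipped convolution blocks* — two convolutions
(standard or depthwise-separable) with an additive shortcut (1x1 projection
when the channel count changes) followed by stride-2 pooling — so a
``(256, 6)`` block becomes a ``(256 / 2**n_blocks, width)`` temporal feature
map.  Each sub-model reads that feature map as a sequence through stacked
recurrent layers (LSTM by default), applies dropout, and emits a single
one-vs-rest sigmoid score for its class.  The predicted class is the argmax
of the per-class scores, with ties broken by event severity.

Reference combiners for comparison experiments are also provided: a stacked
ensemble (sub-model outputs feeding a final softmax learner) and a
weighted-average fusion of per-class scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .labels import DEFAULT_TIE_BREAK, ClassLabel


@dataclass
class EnsembleSpec:
    """Full architecture hyperparameters.

    Defaults follow the configuration found best in tuning: three width-16
    skipped separable-convolution blocks with max pooling and swish, two
    width-16 LSTM layers per sub-model, dropout 0.5.
    """

    n_classes: int = 3
    head_blocks: int = 3
    head_widths: tuple[int, ...] = (16, 16, 16)
    conv_type: str = "separable"            # standard | separable
    pooling: str = "max"                    # max | average
    activation: str = "swish"               # relu | swish
    recurrent_layers: int = 2
    recurrent_widths: tuple[int, ...] = (16, 16)
    recurrent_cell: str = "lstm"            # lstm | gru | bilstm
    dropout_rate: float = 0.5
    kernel_size: int = 5
    input_shape: tuple[int, int] = (256, 6)

    def __post_init__(self) -> None:
        self.head_widths = tuple(self.head_widths)
        self.recurrent_widths = tuple(self.recurrent_widths)
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.head_widths) != self.head_blocks:
            raise ValueError("len(head_widths) must equal head_blocks")
        if len(self.recurrent_widths) != self.recurrent_layers:
            raise ValueError("len(recurrent_widths) must equal recurrent_layers")
        if self.conv_type not in ("standard", "separable"):
            raise ValueError(f"unknown conv_type {self.conv_type!r}")
        if self.recurrent_cell not in nn.RECURRENT_CELLS:
            raise ValueError(f"unknown recurrent_cell {self.recurrent_cell!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def feature_shape(self) -> tuple[int, int]:
        """Shape of the head's output feature map (timesteps, channels)."""
        W, C = self.input_shape
        if self.head_blocks == 0:
            return (W, C)
        if W % (2 ** self.head_blocks):
            raise ValueError(
                f"block width {W} not divisible by 2**{self.head_blocks}"
            )
        return (W // 2 ** self.head_blocks, self.head_widths[-1])


def _conv(spec: EnsembleSpec, in_ch: int, out_ch: int, rng) -> nn.Layer:
    cls = nn.SeparableConv1D if spec.conv_type == "separable" else nn.Conv1D
    return cls(in_ch, out_ch, spec.kernel_size, rng)


class ResidualBlock:
    """conv -> activation -> conv, additive shortcut, stride-2 pooling."""

    def __init__(self, spec: EnsembleSpec, in_ch: int, out_ch: int, rng) -> None:
        self.conv1 = _conv(spec, in_ch, out_ch, rng)
        self.act = nn.Activation(spec.activation)
        self.conv2 = _conv(spec, out_ch, out_ch, rng)
        self.proj = (
            nn.Conv1D(in_ch, out_ch, 1, rng) if in_ch != out_ch else None
        )
        self.pool = nn.Pool1D(spec.pooling)

    @property
    def layers(self) -> list[nn.Layer]:
        ls = [self.conv1, self.act, self.conv2, self.pool]
        if self.proj is not None:
            ls.insert(3, self.proj)
        return ls

    def forward(self, x, training=False):
        h = self.conv2.forward(self.act.forward(self.conv1.forward(x, training), training), training)
        s = self.proj.forward(x, training) if self.proj is not None else x
        return self.pool.forward(h + s, training)

    def backward(self, dy):
        d = self.pool.backward(dy)
        dx = self.conv1.backward(self.act.backward(self.conv2.backward(d)))
        dx = dx + (self.proj.backward(d) if self.proj is not None else d)
        return dx


class HeadModel:
    """Shared convolutional feature extractor (identity when 0 blocks)."""

    def __init__(self, spec: EnsembleSpec, rng: np.random.Generator) -> None:
        spec.feature_shape  # validates divisibility at build time
        self.spec = spec
        self.blocks: list[ResidualBlock] = []
        in_ch = spec.input_shape[1]
        for width in spec.head_widths:
            self.blocks.append(ResidualBlock(spec, in_ch, width, rng))
            in_ch = width

    @property
    def layers(self) -> list[nn.Layer]:
        return [lay for blk in self.blocks for lay in blk.layers]

    def forward(self, x, training=False):
        for blk in self.blocks:
            x = blk.forward(x, training)
        return x

    def backward(self, dy):
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        return dy

    @property
    def n_params(self) -> int:
        return nn.count_params(self.layers)


class SubModel:
    """One per-class branch: recurrent stack -> dropout -> sigmoid unit."""

    def __init__(self, spec: EnsembleSpec, in_dim: int, rng) -> None:
        cell = nn.RECURRENT_CELLS[spec.recurrent_cell]
        self.rnns: list[nn.Layer] = []
        dim = in_dim
        for j, width in enumerate(spec.recurrent_widths):
            last = j == len(spec.recurrent_widths) - 1
            layer = cell(dim, width, rng, return_sequences=not last)
            self.rnns.append(layer)
            dim = layer.out_dim
        self.dropout = nn.Dropout(spec.dropout_rate)
        self.out = nn.Dense(dim, 1, rng)

    @property
    def layers(self) -> list[nn.Layer]:
        return [*self.rnns, self.dropout, self.out]

    def forward(self, feat, training=False):
        h = feat
        for r in self.rnns:
            h = r.forward(h, training)
        if h.ndim == 3:  # no recurrent layers configured: pool over time
            h = h.mean(axis=1)
            self._pooled_T = feat.shape[1]
        return self.out.forward(self.dropout.forward(h, training), training)

    def backward(self, dy):
        d = self.dropout.backward(self.out.backward(dy))
        if not self.rnns:
            d = np.repeat(d[:, None, :], self._pooled_T, axis=1) / self._pooled_T
        for r in reversed(self.rnns):
            d = r.backward(d)
        return d

    @property
    def n_params(self) -> int:
        return nn.count_params(self.layers)


class ClassEnsembleNetwork:
    """Shared head + one binary sub-model per class; argmax fusion.

    ``forward`` returns logits ``(B, n_classes)``; ``scores`` applies the
    sigmoid so each column is a one-vs-rest probability (no sum-to-one
    constraint across classes).
    """

    def __init__(self, spec: EnsembleSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.head = HeadModel(spec, rng)
        feat_dim = spec.feature_shape[1]
        self.submodels = [
            SubModel(spec, feat_dim, rng) for _ in range(spec.n_classes)
        ]

    # -- plumbing ----------------------------------------------------------
    @property
    def layers(self) -> list[nn.Layer]:
        return self.head.layers + [
            lay for sm in self.submodels for lay in sm.layers
        ]

    def seed_dropout(self, rng: np.random.Generator) -> None:
        for lay in self.layers:
            if isinstance(lay, nn.Dropout):
                lay.rng = rng

    def zero_grad(self) -> None:
        for lay in nn.leaf_layers(self.layers):
            lay.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return nn.get_weights(self.layers)

    def set_weights(self, weights) -> None:
        nn.set_weights(self.layers, weights)

    @property
    def n_params(self) -> int:
        return nn.count_params(self.layers)

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        feat = self.head.forward(x, training)
        return np.concatenate(
            [sm.forward(feat, training) for sm in self.submodels], axis=1
        )

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = None
        for i, sm in enumerate(self.submodels):
            d = sm.backward(dlogits[:, i:i + 1])
            dfeat = d if dfeat is None else dfeat + d
        self.head.backward(dfeat)

    def scores(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x, training=False))


class StackedEnsembleNetwork:
    """Reference stacked ensemble: sub-models on the raw block, their
    sigmoid outputs concatenated into a final dense softmax learner."""

    def __init__(self, spec: EnsembleSpec, rng: np.random.Generator,
                 n_submodels: int | None = None) -> None:
        self.spec = spec
        n_sub = spec.n_classes if n_submodels is None else n_submodels
        in_dim = spec.input_shape[1]
        self.submodels = [SubModel(spec, in_dim, rng) for _ in range(n_sub)]
        self.final = nn.Dense(n_sub, spec.n_classes, rng)

    @property
    def layers(self) -> list[nn.Layer]:
        return [lay for sm in self.submodels for lay in sm.layers] + [self.final]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._sub_sig = nn.sigmoid(np.concatenate(
            [sm.forward(x, training) for sm in self.submodels], axis=1
        ))
        logits = self.final.forward(self._sub_sig, training)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)

    @property
    def n_params(self) -> int:
        return nn.count_params(self.layers)


# --------------------------------------------------------------------------
# Builders and fusion rules
# --------------------------------------------------------------------------

def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def build_head_model(spec: EnsembleSpec, rng=0) -> HeadModel:
    return HeadModel(spec, _as_rng(rng))


def build_class_ensemble(spec: EnsembleSpec, rng=0) -> ClassEnsembleNetwork:
    return ClassEnsembleNetwork(spec, _as_rng(rng))


def build_stacked_ensemble(spec: EnsembleSpec, rng=0,
                           n_submodels: int | None = None) -> StackedEnsembleNetwork:
    return StackedEnsembleNetwork(spec, _as_rng(rng), n_submodels=n_submodels)


def fuse_proposed(
    scores: Sequence[float] | np.ndarray,
    tie_break_priority: tuple[ClassLabel, ...] = DEFAULT_TIE_BREAK,
) -> ClassLabel:
    """Argmax over per-class scores; ties resolved by event severity."""
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise ValueError("NaN score passed to fusion")
    best = s.max()
    tied = {int(i) for i in np.nonzero(s == best)[0]}
    for cls in tie_break_priority:
        if int(cls) in tied:
            return cls
    # classes beyond the named three: fall back to lowest tied index
    return ClassLabel(min(tied)) if min(tied) < len(ClassLabel) else min(tied)


def fuse_weighted_average(
    scores: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray,
    tie_break_priority: tuple[ClassLabel, ...] = DEFAULT_TIE_BREAK,
) -> ClassLabel:
    """Argmax of element-wise weighted scores (weights >= 0)."""
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != s.shape:
        raise ValueError(f"weights shape {w.shape} != scores shape {s.shape}")
    if (w < 0).any():
        raise ValueError("ensemble weights must be non-negative")
    return fuse_proposed(s * w, tie_break_priority)


def fuse_batch(scores: np.ndarray,
               tie_break_priority=DEFAULT_TIE_BREAK) -> np.ndarray:
    """Vectorised argmax-with-severity-tie-break over an (n, C) score matrix."""
    return np.asarray(
        [int(fuse_proposed(row, tie_break_priority)) for row in scores],
        dtype=np.int8,
    )


# Closed-form parameter counts (independent oracles for the engine).

def lstm_param_count(units: int, in_dim: int) -> int:
    return 4 * (units * (units + in_dim) + units)


def gru_param_count(units: int, in_dim: int) -> int:
    return 3 * (units * (units + in_dim) + units)
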