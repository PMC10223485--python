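"""Minimal numpy neural-network engine used by the ensemble architecture.

Implements exactly the layer set the fall-detection architecture needs —
1-D standard and depthwise-separable convolutions, max/average pooling,
ReLU/Swish activations, LSTM/GRU/bidirectional-LSTM recurrent layers,
dropout, dense heads — each with a hand-derived backward pass, plus the
Adam optimizer.  Everything is deterministic given a ``numpy.random
.Generator``.

Array convention: batches are ``(B, T, C)`` (batch, timesteps, channels);
recurrent layers reduce to ``(B, units)`` when ``return_sequences`` is
false.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    n = max(rows, cols)
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols]


class Layer:
    """Base: trainable arrays live in ``params`` with matching ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


# --------------------------------------------------------------------------
# Convolutions ('same' padding, stride 1)
# --------------------------------------------------------------------------

def _pad_same(x: np.ndarray, k: int) -> tuple[np.ndarray, int, int]:
    left = (k - 1) // 2
    right = k - 1 - left
    return np.pad(x, ((0, 0), (left, right), (0, 0))), left, right


class Conv1D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        k = kernel_size
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch
        self.params = {
            "W": _glorot(rng, (k * in_ch, out_ch), k * in_ch, k * out_ch),
            "b": np.zeros(out_ch),
        }
        self.zero_grad()

    def _cols(self, x: np.ndarray) -> np.ndarray:
        xp, self._pl, _ = _pad_same(x, self.k)
        # (B, T, C, k) -> (B, T, k, C) -> (B, T, k*C), ordering matches W
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], x.shape[1], self.k * self.in_ch
        )

    def forward(self, x, training=False):
        self._x_shape = x.shape
        self._cols_cache = self._cols(x)
        return self._cols_cache @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        B, T, _ = self._x_shape
        cols2 = self._cols_cache.reshape(B * T, -1)
        dy2 = dy.reshape(B * T, self.out_ch)
        self.grads["W"] += cols2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        dcols = (dy2 @ self.params["W"].T).reshape(B, T, self.k, self.in_ch)
        dxp = np.zeros((B, T + self.k - 1, self.in_ch))
        for j in range(self.k):
            dxp[:, j:j + T, :] += dcols[:, :, j, :]
        return dxp[:, self._pl:self._pl + T, :]


class SeparableConv1D(Layer):
    """Depthwise (one filter per channel) then pointwise 1x1 convolution."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        k = kernel_size
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch
        self.params = {
            "Wd": _glorot(rng, (k, in_ch), k, k),
            "Wp": _glorot(rng, (in_ch, out_ch), in_ch, out_ch),
            "b": np.zeros(out_ch),
        }
        self.zero_grad()

    def forward(self, x, training=False):
        B, T, C = x.shape
        xp, self._pl, _ = _pad_same(x, self.k)
        self._win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # depthwise: (B,T,C,k) x (k,C) summed over k
        self._depth = np.einsum("btck,kc->btc", self._win, self.params["Wd"])
        self._x_shape = x.shape
        return self._depth @ self.params["Wp"] + self.params["b"]

    def backward(self, dy):
        B, T, C = self._x_shape
        dy2 = dy.reshape(B * T, self.out_ch)
        self.grads["Wp"] += self._depth.reshape(B * T, C).T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        ddepth = dy @ self.params["Wp"].T                     # (B,T,C)
        self.grads["Wd"] += np.einsum("btck,btc->kc", self._win, ddepth)
        dxp = np.zeros((B, T + self.k - 1, C))
        for j in range(self.k):
            dxp[:, j:j + T, :] += ddepth * self.params["Wd"][j][None, None, :]
        return dxp[:, self._pl:self._pl + T, :]


# --------------------------------------------------------------------------
# Pooling, activations, dropout, dense
# --------------------------------------------------------------------------

class Pool1D(Layer):
    """Non-overlapping max or average pooling with window = stride = 2."""

    def __init__(self, mode: str = "max", size: int = 2) -> None:
        super().__init__()
        if mode not in ("max", "average"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.mode, self.size = mode, size

    def forward(self, x, training=False):
        B, T, C = x.shape
        if T % self.size:
            raise ValueError(f"temporal length {T} not divisible by pool size {self.size}")
        r = x.reshape(B, T // self.size, self.size, C)
        self._in_shape = x.shape
        if self.mode == "max":
            self._argmax = r.argmax(axis=2)
            return r.max(axis=2)
        return r.mean(axis=2)

    def backward(self, dy):
        B, T, C = self._in_shape
        out = np.zeros((B, T // self.size, self.size, C))
        if self.mode == "max":
            np.put_along_axis(out, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        else:
            out += (dy / self.size)[:, :, None, :]
        return out.reshape(B, T, C)


class Activation(Layer):
    def __init__(self, kind: str) -> None:
        super().__init__()
        if kind not in ("relu", "swish"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training=False):
        self._x = x
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        self._s = sigmoid(x)
        return x * self._s

    def backward(self, dy):
        if self.kind == "relu":
            return dy * (self._x > 0)
        s = self._s
        return dy * (s + self._x * s * (1.0 - s))


class Dropout(Layer):
    """Inverted dropout; a Generator is attached by the training loop."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params = {
            "W": _glorot(rng, (in_dim, out_dim), in_dim, out_dim),
            "b": np.zeros(out_dim),
        }
        self.zero_grad()

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


# --------------------------------------------------------------------------
# Recurrent layers
# --------------------------------------------------------------------------

class LSTM(Layer):
    """Standard LSTM (gate order i, f, g, o) with forget-gate bias 1.

    Trainable parameters: ``4 * (units * (units + in_dim) + units)``.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.return_sequences = return_sequences
        u = units
        b = np.zeros(4 * u)
        b[u:2 * u] = 1.0
        self.params = {
            "W": _glorot(rng, (in_dim, 4 * u), in_dim, 4 * u),
            "U": np.concatenate(
                [_orthogonal(rng, u, u) for _ in range(4)], axis=1),
            "b": b,
        }
        self.zero_grad()

    @property
    def out_dim(self) -> int:
        return self.units

    def forward(self, x, training=False):
        B, T, _ = x.shape
        u = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, u))
        for t in range(T):
            z = x[:, t, :] @ W + h @ U + b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, u))
        dc_next = np.zeros((B, u))
        if self.return_sequences:
            dH = dy
        else:
            dH = np.zeros((B, T, u))
            dH[:, -1, :] = dy
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            da = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dW += x[:, t, :].T @ da
            dU += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t, :] = da @ W.T
            dh_next = da @ U.T
            dc_next = dc * f
        self.grads["W"] += dW
        self.grads["U"] += dU
        self.grads["b"] += db
        return dx


class GRU(Layer):
    """Classic GRU (reset gate applied to the previous hidden state).

    Trainable parameters: ``3 * (units * (units + in_dim) + units)`` —
    strictly fewer than an LSTM of the same width.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.return_sequences = return_sequences
        u = units
        self.params = {
            "W": _glorot(rng, (in_dim, 3 * u), in_dim, 3 * u),
            "U": np.concatenate(
                [_orthogonal(rng, u, u) for _ in range(3)], axis=1),
            "b": np.zeros(3 * u),
        }
        self.zero_grad()

    @property
    def out_dim(self) -> int:
        return self.units

    def forward(self, x, training=False):
        B, T, _ = x.shape
        u = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, u))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, u))
        for t in range(T):
            xt = x[:, t, :]
            z = sigmoid(xt @ W[:, :u] + h @ U[:, :u] + b[:u])
            r = sigmoid(xt @ W[:, u:2 * u] + h @ U[:, u:2 * u] + b[u:2 * u])
            rh = r * h
            hh = np.tanh(xt @ W[:, 2 * u:] + rh @ U[:, 2 * u:] + b[2 * u:])
            h_new = (1.0 - z) * h + z * hh
            self._cache.append((h, z, r, rh, hh))
            h = h_new
            hs[:, t, :] = h
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, u))
        if self.return_sequences:
            dH = dy
        else:
            dH = np.zeros((B, T, u))
            dH[:, -1, :] = dy
        for t in range(T - 1, -1, -1):
            h_prev, z, r, rh, hh = self._cache[t]
            xt = x[:, t, :]
            dh = dH[:, t, :] + dh_next
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dhh * (1.0 - hh ** 2)
            drh = da_h @ U[:, 2 * u:].T
            dr = drh * h_prev
            dh_prev += drh * r
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            dW[:, :u] += xt.T @ da_z
            dW[:, u:2 * u] += xt.T @ da_r
            dW[:, 2 * u:] += xt.T @ da_h
            dU[:, :u] += h_prev.T @ da_z
            dU[:, u:2 * u] += h_prev.T @ da_r
            dU[:, 2 * u:] += rh.T @ da_h
            db[:u] += da_z.sum(axis=0)
            db[u:2 * u] += da_r.sum(axis=0)
            db[2 * u:] += da_h.sum(axis=0)
            dx[:, t, :] = (
                da_z @ W[:, :u].T + da_r @ W[:, u:2 * u].T + da_h @ W[:, 2 * u:].T
            )
            dh_next = dh_prev + da_z @ U[:, :u].T + da_r @ U[:, u:2 * u].T
        self.grads["W"] += dW
        self.grads["U"] += dU
        self.grads["b"] += db
        return dx


class BiLSTM(Layer):
    """Two LSTMs over opposite time directions, features concatenated."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False) -> None:
        super().__init__()
        self.fwd = LSTM(in_dim, units, rng, return_sequences=return_sequences)
        self.bwd = LSTM(in_dim, units, rng, return_sequences=return_sequences)
        self.units = units
        self.return_sequences = return_sequences

    @property
    def out_dim(self) -> int:
        return 2 * self.units

    @property
    def sublayers(self):
        return [self.fwd, self.bwd]

    @property
    def n_params(self) -> int:
        return self.fwd.n_params + self.bwd.n_params

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    def forward(self, x, training=False):
        yf = self.fwd.forward(x, training)
        yb = self.bwd.forward(x[:, ::-1, :], training)
        if self.return_sequences:
            yb = yb[:, ::-1, :]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        u = self.units
        dyf, dyb = dy[..., :u], dy[..., u:]
        if self.return_sequences:
            dyb = dyb[:, ::-1, :]
        dxf = self.fwd.backward(dyf)
        dxb = self.bwd.backward(dyb)[:, ::-1, :]
        return dxf + dxb


RECURRENT_CELLS = {"lstm": LSTM, "gru": GRU, "bilstm": BiLSTM}


# --------------------------------------------------------------------------
# Composite helpers and the optimizer
# --------------------------------------------------------------------------

def leaf_layers(layers) -> list[Layer]:
    """Flatten composites (BiLSTM) into the list of parameter-holding leaves."""
    out: list[Layer] = []
    for layer in layers:
        if isinstance(layer, BiLSTM):
            out.extend(layer.sublayers)
        else:
            out.append(layer)
    return out


def get_weights(layers) -> list[np.ndarray]:
    return [
        p.copy() for lay in leaf_layers(layers)
        for _, p in sorted(lay.params.items())
    ]


def set_weights(layers, weights: list[np.ndarray]) -> None:
    it = iter(weights)
    for lay in leaf_layers(layers):
        for k in sorted(lay.params):
            lay.params[k] = next(it).copy()


def count_params(layers) -> int:
    return sum(lay.n_params for lay in leaf_layers(layers))


class Adam:
    """Adam with bias correction over every parameter of the given layers."""

    def __init__(self, layers, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.layers = leaf_layers(layers)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(p) for k, p in lay.params.items()}
            for lay in self.layers
        ]
        self.v = [
            {k: np.zeros_like(p) for k, p in lay.params.items()}
            for lay in self.layers
        ]

    def zero_grad(self) -> None:
        for lay in self.layers:
            lay.zero_grad()

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)
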