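"""Minimal NumPy neural-network backbone for the two-stream bite classifier.

Implements exactly the pieces the detector architecture needs — temporal
(1-D) convolution with same-padding, ReLU, max pooling, LSTM layers, dense
layers, inverted dropout, a weighted sigmoid/cross-entropy loss and Adam —
with hand-written backward passes.  Gradient correctness is covered by a
numerical-differencing test in the suite.

Shapes follow the (batch, time, channels) convention.  All randomness
(initialization, shuffling, dropout) flows through explicitly passed
``numpy.random.Generator`` objects, so training is bit-reproducible on a
fixed seed with single-threaded BLAS.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import expit as sigmoid

__all__ = [
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "LSTM",
    "Dense",
    "Dropout",
    "Sequential",
    "TwoStreamNet",
    "Adam",
    "weighted_bce_with_logits",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Temporal convolution with zero same-padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd (same-padding)")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params["W"] = _glorot(rng, kernel * c_in, c_out, (kernel * c_in, c_out))
        self.params["b"] = np.zeros(c_out)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        return np.concatenate([xp[:, i : i + T, :] for i in range(self.kernel)], axis=2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = self._im2col(x)
        self._cache = (x.shape, cols)
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, T, C), cols = self._cache
        W = self.params["W"]
        self.grads["W"] = cols.reshape(-1, W.shape[0]).T @ dout.reshape(-1, self.c_out)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dcols = dout @ W.T  # (B, T, k*C)
        p = self.kernel // 2
        dxp = np.zeros((B, T + 2 * p, C))
        for i in range(self.kernel):
            dxp[:, i : i + T, :] += dcols[:, :, i * C : (i + 1) * C]
        return dxp[:, p : p + T, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, C = x.shape
        Tp = T // self.pool
        xr = x[:, : Tp * self.pool, :].reshape(B, Tp, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = (B, T, C)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self._shape
        Tp = T // self.pool
        dxr = np.zeros((B, Tp, self.pool, C))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((B, T, C))
        dx[:, : Tp * self.pool, :] = dxr.reshape(B, Tp * self.pool, C)
        return dx


class LSTM(Layer):
    """Single LSTM layer; gate order (input, forget, cell, output).

    ``return_sequences=False`` emits only the final hidden state.  Forget
    gate bias initialized to 1.
    """

    def __init__(
        self,
        c_in: int,
        units: int,
        rng: np.random.Generator,
        return_sequences: bool = True,
    ):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        H = units
        self.params["Wx"] = _glorot(rng, c_in, 4 * H, (c_in, 4 * H))
        self.params["Wh"] = _glorot(rng, H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        self.params["b"] = b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        xz = x @ Wx  # precompute input contribution, (B, T, 4H)
        self._steps = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = xz[:, t, :] + h @ Wh + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._steps.append((h, c, i, f, g, o, tc))
            h, c = o * tc, c_new
            hs[:, t, :] = h
        self._x = x
        return hs if self.return_sequences else h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, C = x.shape
        H = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._steps[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, t, :]
            elif t == T - 1:
                dh += dout
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, c_in, c_out, (c_in, c_out))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for idx, layer in enumerate(self.layers):
            for name in layer.params:
                yield (idx, name), layer

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for (_, name), layer in self.parameters())


def _build_stream(
    c_in: int,
    conv_blocks: Sequence[tuple[int, int]],
    pool_size: int,
    lstm_units: Sequence[int],
    rng: np.random.Generator,
) -> Sequential:
    layers: list[Layer] = []
    c = c_in
    for filters, kernel in conv_blocks:
        layers += [Conv1D(c, filters, kernel, rng), ReLU()]
        layers += [Conv1D(filters, filters, kernel, rng), ReLU()]
        layers.append(MaxPool1D(pool_size))
        c = filters
    for li, units in enumerate(lstm_units):
        last = li == len(lstm_units) - 1
        layers.append(LSTM(c, units, rng, return_sequences=not last))
        c = units
    return Sequential(layers)


class TwoStreamNet:
    """Two-stream temporal classifier: per-stream conv blocks + LSTM stack,
    streams concatenated and fused by a dense layer into one bite logit.

    Each stream applies two convolutional blocks (two same-padded temporal
    convolutions + ReLU, then max pooling), followed by a stack of LSTM
    layers whose final hidden state summarizes the window.  The body and
    mouth summaries are concatenated and passed through a fused dense layer
    and a linear output head; the bite probability is the sigmoid of the
    returned logit.
    """

    def __init__(
        self,
        body_dim: int,
        mouth_dim: int,
        conv_blocks: Sequence[tuple[int, int]] = ((32, 3), (64, 3)),
        pool_size: int = 2,
        lstm_units: Sequence[int] = (64, 32),
        fusion_units: int = 32,
        dropout: float = 0.1,
        seed: int = 0,
    ):
        if len(conv_blocks) != 2:
            raise ValueError("the architecture uses exactly two conv blocks per stream")
        if len(lstm_units) < 1:
            raise ValueError("need at least one LSTM layer")
        ss = np.random.SeedSequence(seed)
        r_body, r_mouth, r_head, r_drop = (np.random.default_rng(s) for s in ss.spawn(4))
        self.body = _build_stream(body_dim, conv_blocks, pool_size, lstm_units, r_body)
        self.mouth = _build_stream(mouth_dim, conv_blocks, pool_size, lstm_units, r_mouth)
        joint = 2 * lstm_units[-1]
        self.head = Sequential(
            [
                Dense(joint, fusion_units, r_head),
                ReLU(),
                Dropout(dropout, r_drop),
                Dense(fusion_units, 1, r_head),
            ]
        )
        self._split = lstm_units[-1]

    def forward(self, xb: np.ndarray, xm: np.ndarray, train: bool = False) -> np.ndarray:
        hb = self.body.forward(xb, train=train)
        hm = self.mouth.forward(xm, train=train)
        logits = self.head.forward(np.concatenate([hb, hm], axis=1), train=train)
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        djoint = self.head.backward(dlogits[:, None])
        self.body.backward(djoint[:, : self._split])
        self.mouth.backward(djoint[:, self._split :])

    def predict_proba(self, xb: np.ndarray, xm: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty(xb.shape[0])
        for s in range(0, xb.shape[0], batch_size):
            out[s : s + batch_size] = sigmoid(
                self.forward(xb[s : s + batch_size], xm[s : s + batch_size], train=False)
            )
        return out

    def modules(self) -> list[Sequential]:
        return [self.body, self.mouth, self.head]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for mi, mod in enumerate(self.modules()):
            for (li, name), layer in mod.parameters():
                state[f"m{mi}.l{li}.{name}"] = layer.params[name]
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for mi, mod in enumerate(self.modules()):
            for (li, name), layer in mod.parameters():
                layer.params[name] = np.asarray(state[f"m{mi}.l{li}.{name}"])


def weighted_bce_with_logits(
    logits: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    B = logits.shape[0]
    w = np.ones(B) if weights is None else weights
    p = sigmoid(logits)
    # log-sum-exp form, stable for large |logits|
    ll = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    loss = float(np.mean(w * ll))
    dlogits = w * (p - y) / B
    return loss, dlogits


class Adam:
    def __init__(self, net: TwoStreamNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple, np.ndarray] = {}
        self.v: dict[tuple, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for mi, mod in enumerate(self.net.modules()):
            for (li, name), layer in mod.parameters():
                key = (mi, li, name)
                g = layer.grads.get(name)
                if g is None:
                    continue
                if key not in self.m:
                    self.m[key] = np.zeros_like(g)
                    self.v[key] = np.zeros_like(g)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
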