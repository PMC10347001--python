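"""NumPy building blocks for the LSTM-CNN classifier.

Each layer implements the forward map and its exact gradient (reverse-mode,
hand-derived), in float32, batched over the leading axis.  The recurrences
and the convolution follow the standard formulations:

LSTM cell (gates i, f, o and candidate g; elementwise products):

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    g_t = tanh   (W_c x_t + U_c h_{t-1} + b_c)
    C_t = f_t * C_{t-1} + i_t * g_t
    h_t = o_t * tanh(C_t)

Temporal convolution (feature map j of layer l, kernel width 3,
'same' padding, stride 1):

    x_j^l = f( sum_i  x_i^{l-1} * W_j^l + b_j^l ),   f = ReLU

Max pooling is 1-D over the time axis with width 2 ('valid'), and the head
is a single dense layer producing 4 logits.  Adam is the optimizer.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base: subclasses fill ``params`` and matching ``grads`` lists."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class LSTMLayer(Layer):
    """Full-sequence LSTM: (B, T, C) -> (B, T, H), h_0 = C_0 = 0.

    Gate pre-activations are packed as one (.., 4H) block in the fixed
    order [i, f, g, o]; the forget-gate bias starts at 1.
    """

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.Wx = _glorot(rng, (in_dim, 4 * units))
        self.Wh = _glorot(rng, (units, 4 * units))
        self.b = np.zeros(4 * units, dtype=DTYPE)
        self.b[units : 2 * units] = 1.0
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        H = self.units
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        # caches for BPTT
        self._x = x
        self._gates = np.empty((B, T, 4 * H), dtype=DTYPE)
        self._cs = np.empty((B, T, H), dtype=DTYPE)
        self._c_prev = np.empty((B, T, H), dtype=DTYPE)
        self._h_prev = np.empty((B, T, H), dtype=DTYPE)
        xw = x.reshape(B * T, C) @ self.Wx  # all input projections at once
        xw = xw.reshape(B, T, 4 * H)
        for t in range(T):
            z = xw[:, t] + h @ self.Wh + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            self._h_prev[:, t] = h
            self._c_prev[:, t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            self._gates[:, t, :H] = i
            self._gates[:, t, H : 2 * H] = f
            self._gates[:, t, 2 * H : 3 * H] = g
            self._gates[:, t, 3 * H :] = o
            self._cs[:, t] = c
            hs[:, t] = h
        return hs

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, C = x.shape
        H = self.units
        dWx, dWh, db = self.grads
        dWx[...] = 0.0
        dWh[...] = 0.0
        db[...] = 0.0
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        dz_all = np.empty((B, T, 4 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i = self._gates[:, t, :H]
            f = self._gates[:, t, H : 2 * H]
            g = self._gates[:, t, 2 * H : 3 * H]
            o = self._gates[:, t, 3 * H :]
            c = self._cs[:, t]
            tanh_c = np.tanh(c)
            dh = dout[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tanh_c * tanh_c)
            dz = dz_all[:, t]
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H : 2 * H] = dc * self._c_prev[:, t] * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dc * i * (1.0 - g * g)
            dz[:, 3 * H :] = dh * tanh_c * o * (1.0 - o)
            dWh += self._h_prev[:, t].T @ dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        flat_dz = dz_all.reshape(B * T, 4 * H)
        dWx += x.reshape(B * T, C).T @ flat_dz
        db += flat_dz.sum(axis=0)
        dx[...] = (flat_dz @ self.Wx.T).reshape(B, T, C)
        return dx


class Conv1D(Layer):
    """Temporal convolution, 'same' padding, stride 1, ReLU activation.

    (B, T, Cin) -> (B, T, Cout) with kernel width ``width`` (odd).
    """

    def __init__(
        self, in_channels: int, out_channels: int, width: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        if width % 2 != 1:
            raise ValueError("kernel width must be odd for 'same' padding")
        self.width = width
        self.in_channels, self.out_channels = in_channels, out_channels
        self.W = _glorot(rng, (width * in_channels, out_channels))
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        pad = self.width // 2
        xp = np.zeros((B, T + 2 * pad, C), dtype=DTYPE)
        xp[:, pad : pad + T] = x
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.width, axis=1)
        # (B, T, C, width) -> (B, T, width*C) matching W's (width*C) layout
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(
            B, T, self.width * C
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        self._cols = self._im2col(x)
        pre = self._cols @ self.W + self.b
        self._mask = pre > 0
        self._in_shape = x.shape
        return np.where(self._mask, pre, 0.0).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        dpre = np.where(self._mask, dout, 0.0).astype(DTYPE, copy=False)
        dW, db = self.grads
        flat_cols = self._cols.reshape(B * T, -1)
        flat_dpre = dpre.reshape(B * T, -1)
        dW[...] = flat_cols.T @ flat_dpre
        db[...] = flat_dpre.sum(axis=0)
        dcols = (flat_dpre @ self.W.T).reshape(B, T, self.width, C)
        pad = self.width // 2
        dxp = np.zeros((B, T + 2 * pad, C), dtype=DTYPE)
        for k in range(self.width):
            dxp[:, k : k + T] += dcols[:, :, k]
        return dxp[:, pad : pad + T]


class MaxPool1D(Layer):
    """1-D max pooling over time, width 2, 'valid'; configurable stride."""

    def __init__(self, width: int = 2, stride: int = 2) -> None:
        super().__init__()
        self.width, self.stride = width, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        T_out = (T - self.width) // self.stride + 1
        if T_out < 1:
            raise ValueError(f"time length {T} too short for pooling")
        starts = np.arange(T_out) * self.stride
        windows = np.stack(
            [x[:, s : s + self.width] for s in starts], axis=1
        )  # (B, T_out, width, C)
        self._arg = windows.argmax(axis=2)  # (B, T_out, C)
        self._in_shape = x.shape
        self._starts = starts
        return windows.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, C = self._in_shape
        dx = np.zeros((B, T, C), dtype=DTYPE)
        bi = np.arange(B)[:, None]
        ci = np.arange(C)[None, :]
        for j, s in enumerate(self._starts):
            # overlapping windows (stride < width) must accumulate
            np.add.at(dx, (bi, s + self._arg[:, j], ci), dout[:, j])
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    """Affine layer producing logits (no activation)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, (in_dim, out_dim))
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dW, db = self.grads
        dW[...] = self._x.T @ dout
        db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(B), labels] + eps)))
    dlogits = probs
    dlogits[np.arange(B), labels] -= 1.0
    return loss, (dlogits / B).astype(DTYPE)


class Adam:
    """Adam with the usual bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2**self.t) / (1.0 - self.b1**self.t)
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
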