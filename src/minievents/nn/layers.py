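"""Minimal NumPy layers with forward/backward passes.

Implements exactly the layer types needed by the window classifier:
1-D convolution (same padding), batch normalization, leaky ReLU,
average pooling, bidirectional LSTM with sum merge, dense and dropout.
All parameters are float32; gradients are accumulated per mini-batch.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Param", "Layer", "Conv1D", "BatchNorm1D", "LeakyReLU", "AvgPool1D",
    "BiLSTM", "Dense", "Dropout", "glorot_uniform", "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable and single-pass: sigmoid(x) = (1 + tanh(x/2)) / 2
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Param:
    """A parameter tensor with its gradient and trainability flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True,
                 name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Param({self.name}, shape={self.value.shape}, "
                f"trainable={self.trainable})")


class Layer:
    params: list

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution with 'same' padding and unit stride.

    Input (B, L, C_in) -> output (B, L, C_out).  Odd kernel sizes only.
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv"):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * filters
        self.W = Param(glorot_uniform(rng, (kernel_size, in_channels, filters),
                                      fan_in, fan_out), name=f"{name}.kernel")
        self.b = Param(np.zeros(filters, dtype=DTYPE), name=f"{name}.bias")
        self.params = [self.W, self.b]
        self._cache = None

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # im2col by shifted slices (contiguous inner axis -> fast copies)
        col = np.empty((B, L, k, C), dtype=DTYPE)
        for j in range(k):
            col[:, :, j, :] = xp[:, j:j + L, :]
        col2 = col.reshape(B * L, k * C)
        Wm = self.W.value.reshape(k * C, self.filters)
        y = col2 @ Wm + self.b.value
        self._cache = (col2 if training else None, (B, L, C))
        return y.reshape(B, L, self.filters)

    def backward(self, dy):
        col2, (B, L, C) = self._cache
        k = self.kernel_size
        pad = k // 2
        dy2 = dy.reshape(B * L, self.filters)
        Wm = self.W.value.reshape(k * C, self.filters)
        self.W.grad += (col2.T @ dy2).reshape(self.W.value.shape)
        self.b.grad += dy2.sum(axis=0)
        dcol = (dy2 @ Wm.T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + 2 * pad, C), dtype=DTYPE)
        for j in range(k):
            dxp[:, j:j + L, :] += dcol[:, :, j, :]
        return dxp[:, pad:pad + L, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over batch and length axes.

    Scale/offset are trainable; moving mean/variance are tracked but
    non-trainable.  When ``frozen`` the layer always normalizes with the
    moving statistics and never updates them (used for transfer learning).
    """

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-3, name: str = "bn"):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.frozen = False
        self.gamma = Param(np.ones(channels, dtype=DTYPE), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=DTYPE), name=f"{name}.beta")
        self.moving_mean = Param(np.zeros(channels, dtype=DTYPE),
                                 trainable=False, name=f"{name}.moving_mean")
        self.moving_var = Param(np.ones(channels, dtype=DTYPE),
                                trainable=False, name=f"{name}.moving_var")
        self.params = [self.gamma, self.beta, self.moving_mean, self.moving_var]
        self._cache = None

    def forward(self, x, training=False, rng=None):
        batch_stats = training and not self.frozen
        if batch_stats:
            mean = x.mean(axis=(0, 1), dtype=np.float64).astype(DTYPE)
            var = x.var(axis=(0, 1), dtype=np.float64).astype(DTYPE)
            m = self.momentum
            self.moving_mean.value = (m * self.moving_mean.value
                                      + (1 - m) * mean).astype(DTYPE)
            self.moving_var.value = (m * self.moving_var.value
                                     + (1 - m) * var).astype(DTYPE)
        else:
            mean = self.moving_mean.value
            var = self.moving_var.value
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        if not training:
            # fused affine fast path; nothing cached for backward
            a = self.gamma.value * ivar
            self._cache = None
            return x * a + (self.beta.value - mean * a)
        xhat = (x - mean) * ivar
        self._cache = (xhat, ivar, batch_stats)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, ivar, batch_stats = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        g = self.gamma.value * ivar
        if not batch_stats:
            return dy * g
        N = dy.shape[0] * dy.shape[1]
        s1 = dy.sum(axis=(0, 1))
        s2 = (dy * xhat).sum(axis=(0, 1))
        return (g / N) * (N * dy - s1 - xhat * s2)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        super().__init__()
        self.alpha = alpha
        self._dmask = None

    def forward(self, x, training=False, rng=None):
        if training:
            m = (x > 0).astype(DTYPE)
            m *= (1.0 - self.alpha)
            m += self.alpha
            self._dmask = m
            return x * m
        return self.alpha * x + (1.0 - self.alpha) * np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._dmask


class AvgPool1D(Layer):
    """Non-overlapping average pooling (pool size == stride)."""

    def __init__(self, pool_size: int):
        super().__init__()
        self.pool_size = pool_size
        self._shape = None

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        p = self.pool_size
        if L % p:
            raise ValueError(f"length {L} not divisible by pool size {p}")
        self._shape = (B, L, C)
        return x.reshape(B, L // p, p, C).mean(axis=2, dtype=DTYPE)

    def backward(self, dy):
        B, L, C = self._shape
        p = self.pool_size
        return (np.repeat(dy, p, axis=1) / p).astype(DTYPE)


class Dense(Layer):
    def __init__(self, in_features: int, units: int,
                 rng: np.random.Generator, name: str = "dense"):
        super().__init__()
        self.W = Param(glorot_uniform(rng, (in_features, units),
                                      in_features, units), name=f"{name}.kernel")
        self.b = Param(np.zeros(units, dtype=DTYPE), name=f"{name}.bias")
        self.params = [self.W, self.b]
        self._x = None

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BiLSTM(Layer):
    """Bidirectional LSTM, sum-merged, returning the final hidden state.

    Both directions are stepped together as a leading axis of size two so
    each time step issues a single batched matmul.  Gate layout along the
    last weight axis is (input, forget, output, cell); the forget-gate
    bias starts at one.  Input dropout (one mask per direction, shared
    across time steps) is applied during training.
    """

    def __init__(self, in_features: int, units: int, dropout: float,
                 rng: np.random.Generator, name: str = "lstm"):
        super().__init__()
        self.units = units
        self.dropout = dropout
        H = units
        self.Wx = Param(glorot_uniform(rng, (2, in_features, 4 * H),
                                       in_features, 4 * H), name=f"{name}.kernel")
        self.Wh = Param(glorot_uniform(rng, (2, H, 4 * H), H, 4 * H),
                        name=f"{name}.recurrent_kernel")
        b = np.zeros((2, 4 * H), dtype=DTYPE)
        b[:, H:2 * H] = 1.0  # forget gate
        self.b = Param(b, name=f"{name}.bias")
        self.params = [self.Wx, self.Wh, self.b]
        self._cache = None

    def forward(self, x, training=False, rng=None):
        B, T, F = x.shape
        H = self.units
        if training and self.dropout > 0:
            keep = 1.0 - self.dropout
            masks = (rng.random((2, B, 1, F)) < keep).astype(DTYPE) / keep
        else:
            masks = None
        # direction 0 reads time forward, direction 1 reversed
        x2 = np.stack([x, x[:, ::-1]])
        if masks is not None:
            x2 = x2 * masks
        # time-major input projections: z_in[t] is a contiguous (2, B, 4H) view
        xt = np.ascontiguousarray(x2.transpose(2, 0, 1, 3))  # (T, 2, B, F)
        z_in = xt @ self.Wx.value + self.b.value[:, None, :]
        h = np.zeros((2, B, H), dtype=DTYPE)
        c = np.zeros((2, B, H), dtype=DTYPE)
        steps = [] if training else None
        for t in range(T):
            z = z_in[t] + h @ self.Wh.value
            ifo = sigmoid(z[..., :3 * H])
            g = np.tanh(z[..., 3 * H:])
            i = ifo[..., :H]
            f = ifo[..., H:2 * H]
            o = ifo[..., 2 * H:3 * H]
            c_prev = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            if steps is not None:
                steps.append((ifo, g, c_prev, tc, h))
        self._cache = (x2, masks, steps)
        return h[0] + h[1]

    def backward(self, dy):
        x2, masks, steps = self._cache
        _, B, T, F = x2.shape
        H = self.units
        dx2 = np.zeros_like(x2)
        dh = np.stack([dy, dy]).astype(DTYPE)
        dc = np.zeros((2, B, H), dtype=DTYPE)
        dWx = np.zeros_like(self.Wx.value)
        dWh = np.zeros_like(self.Wh.value)
        db = np.zeros_like(self.b.value)
        WhT = self.Wh.value.transpose(0, 2, 1)
        WxT = self.Wx.value.transpose(0, 2, 1)
        dz = np.empty((2, B, 4 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            ifo, g, c_prev, tc, _h = steps[t]
            i = ifo[..., :H]
            f = ifo[..., H:2 * H]
            o = ifo[..., 2 * H:3 * H]
            dc = dc + dh * o * (1.0 - tc * tc)
            dz[..., :H] = (dc * g) * i * (1.0 - i)
            dz[..., H:2 * H] = (dc * c_prev) * f * (1.0 - f)
            dz[..., 2 * H:3 * H] = (dh * tc) * o * (1.0 - o)
            dz[..., 3 * H:] = (dc * i) * (1.0 - g * g)
            h_prev = (steps[t - 1][4] if t > 0
                      else np.zeros((2, B, H), dtype=DTYPE))
            dWx += x2[:, :, t].transpose(0, 2, 1) @ dz
            dWh += h_prev.transpose(0, 2, 1) @ dz
            db += dz.sum(axis=1)
            dx2[:, :, t] = dz @ WxT
            dh = dz @ WhT
            dc = dc * f
        self.Wx.grad += dWx
        self.Wh.grad += dWh
        self.b.grad += db
        if masks is not None:
            dx2 = dx2 * masks
        return dx2[0] + dx2[1, :, ::-1]
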