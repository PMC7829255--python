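"""Layers with explicit forward/backward passes.

Conventions: batched inputs, time-major-within-sample tensors
``(batch, time, channels)`` for sequence layers and ``(batch, features)``
for dense layers.  Every layer caches in ``forward`` exactly what its
``backward`` needs; parameter gradients accumulate into ``Param.grad``.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.velocity = np.zeros_like(value)


class Layer:
    def __init__(self):
        self.params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.W = Param(rng.normal(0.0, std, (in_features, out_features)).astype(dtype))
        self.b = Param(np.zeros(out_features, dtype=dtype))
        self.params = [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv1D(Layer):
    """1-D convolution along time with 'same' zero padding, stride 1."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, kernel_size: int = 3, dtype=np.float32):
        super().__init__()
        self.k = kernel_size
        self.in_channels = in_channels
        fan_in = kernel_size * in_channels
        std = np.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, std, (fan_in, out_channels)).astype(dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self.params = [self.W, self.b]

    def _im2col(self, xp: np.ndarray, T: int) -> np.ndarray:
        # xp: (N, T + k - 1, C) -> (N, T, k*C)
        N, _, C = xp.shape
        cols = np.empty((N, T, self.k * C), dtype=xp.dtype)
        for i in range(self.k):
            cols[:, :, i * C : (i + 1) * C] = xp[:, i : i + T, :]
        return cols

    def forward(self, x, train=False):
        N, T, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, self.k - 1 - p), (0, 0)))
        cols = self._im2col(xp, T)
        self._cols, self._shape = cols, (N, T, C)
        return cols @ self.W.value + self.b.value

    def backward(self, grad):
        N, T, C = self._shape
        p = self.k // 2
        flat = grad.reshape(-1, grad.shape[-1])
        self.W.grad += self._cols.reshape(-1, self.k * C).T @ flat
        self.b.grad += flat.sum(axis=0)
        dcols = grad @ self.W.value.T  # (N, T, k*C)
        dxp = np.zeros((N, T + self.k - 1, C), dtype=grad.dtype)
        for i in range(self.k):
            dxp[:, i : i + T, :] += dcols[:, :, i * C : (i + 1) * C]
        return dxp[:, p : p + T, :]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time (trailing remainder dropped)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        N, T, C = x.shape
        T2 = T // self.pool
        xr = x[:, : T2 * self.pool, :].reshape(N, T2, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = (N, T, C)
        return xr.max(axis=2)

    def backward(self, grad):
        N, T, C = self._shape
        T2 = grad.shape[1]
        dxr = np.zeros((N, T2, self.pool, C), dtype=grad.dtype)
        n_i, t_i, c_i = np.ogrid[:N, :T2, :C]
        dxr[n_i, t_i, self._argmax, c_i] = grad
        dx = np.zeros((N, T, C), dtype=grad.dtype)
        dx[:, : T2 * self.pool, :] = dxr.reshape(N, T2 * self.pool, C)
        return dx


class BatchNorm(Layer):
    """Batch normalisation over the batch (and time, for sequence input)."""

    def __init__(self, n_features: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Param(np.ones(n_features, dtype=dtype))
        self.beta = Param(np.zeros(n_features, dtype=dtype))
        self.params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(x.dtype), axes, int(np.prod([x.shape[a] for a in axes])))
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, axes, m = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        # standard batch-norm gradient through batch statistics
        dx = (inv / m) * (
            m * g - g.sum(axis=axes) - xhat * (g * xhat).sum(axis=axes)
        )
        return dx.astype(grad.dtype)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape1D(Layer):
    """(N, F) -> (N, F, 1): lets a dense output feed 1-D convolutions."""

    def forward(self, x, train=False):
        return x[:, :, None]

    def backward(self, grad):
        return grad[:, :, 0]


class LSTM(Layer):
    """Single LSTM layer; optionally returns the full hidden sequence."""

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False, dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        self.return_sequences = return_sequences
        sw = np.sqrt(1.0 / in_features)
        su = np.sqrt(1.0 / hidden)
        self.W = Param(rng.normal(0, sw, (in_features, 4 * hidden)).astype(dtype))
        self.U = Param(rng.normal(0, su, (hidden, 4 * hidden)).astype(dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Param(b)
        self.params = [self.W, self.U, self.b]

    def forward(self, x, train=False):
        N, T, _ = x.shape
        H = self.hidden
        dt = x.dtype
        i_s = np.empty((T, N, H), dt); f_s = np.empty((T, N, H), dt)
        g_s = np.empty((T, N, H), dt); o_s = np.empty((T, N, H), dt)
        c_s = np.empty((T, N, H), dt); tc_s = np.empty((T, N, H), dt)
        h_s = np.empty((T, N, H), dt)
        h = np.zeros((N, H), dt)
        c = np.zeros((N, H), dt)
        xW = x @ self.W.value + self.b.value  # (N, T, 4H)
        for t in range(T):
            z = xW[:, t, :] + h @ self.U.value
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            i_s[t], f_s[t], g_s[t], o_s[t] = i, f, g, o
            c_s[t], tc_s[t], h_s[t] = c, tc, h
        self._cache = (x, i_s, f_s, g_s, o_s, c_s, tc_s, h_s)
        if self.return_sequences:
            return h_s.transpose(1, 0, 2)
        return h

    def backward(self, grad):
        x, i_s, f_s, g_s, o_s, c_s, tc_s, h_s = self._cache
        N, T, F = x.shape
        H = self.hidden
        dh_seq = grad.transpose(1, 0, 2) if self.return_sequences else None
        dh_next = np.zeros((N, H), grad.dtype) if self.return_sequences else grad.astype(x.dtype)
        dc_next = np.zeros((N, H), x.dtype)
        dz_all = np.empty((T, N, 4 * H), x.dtype)
        for t in range(T - 1, -1, -1):
            dh = dh_next + (dh_seq[t] if dh_seq is not None else 0.0)
            i, f, g, o = i_s[t], f_s[t], g_s[t], o_s[t]
            tc = tc_s[t]
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            c_prev = c_s[t - 1] if t > 0 else np.zeros_like(dc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dz_all[t] = dz
            dh_next = dz @ self.U.value.T
        # parameter gradients in one batched contraction
        dz_btf = dz_all.transpose(1, 0, 2)  # (N, T, 4H)
        self.W.grad += np.einsum("ntf,nth->fh", x, dz_btf)
        h_prev = np.concatenate([np.zeros((1, N, H), x.dtype), h_s[:-1]], axis=0)
        self.U.grad += np.einsum("tnh,tnk->hk", h_prev, dz_all)
        self.b.grad += dz_all.sum(axis=(0, 1))
        return dz_btf @ self.W.value.T
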