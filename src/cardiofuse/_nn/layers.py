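"""Minimal layer zoo with manual backpropagation.

Tensors are channels-last: 1D signals are (N, L, C), spectrogram images
are (N, H, W, C). This layout lets convolutions run as a shift-and-add of
batched GEMMs (``x[:, j:j+L] @ W[j]``) with no transposes or im2col
copies, which is what keeps CPU training of the branch networks fast.

Every layer caches what its backward pass needs during ``forward``. A
layer owns its parameters (``params`` dict) and accumulates gradients of
the same shapes in ``grads``. Setting ``frozen`` excludes a layer's
parameters from optimizer updates while still letting gradients flow
through it (required for freezing early convolutional blocks during
transfer learning).

Convolutions are stride-1 with "same" zero padding; pooling layers use
kernel == stride (non-overlapping windows), truncating a trailing partial
window.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: parameter-free identity."""

    frozen = False

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d(Layer):
    """Stride-1 same-padded 1D convolution on (N, L, C) tensors."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = kernel // 2
        self.params = {
            "W": _he_init(rng, (kernel, in_ch, out_ch), in_ch * kernel, dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }

    def forward(self, x, training=False):
        W = self.params["W"]
        L = x.shape[1]
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        self._xp, self._L = xp, L
        y = np.matmul(xp[:, 0:L, :], W[0])
        for j in range(1, self.kernel):
            y += np.matmul(xp[:, j:j + L, :], W[j])
        return y + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        xp, L = self._xp, self._L
        self.grads["b"] = dy.sum(axis=(0, 1))
        dW = np.empty_like(W)
        for j in range(self.kernel):
            dW[j] = np.tensordot(xp[:, j:j + L, :], dy, axes=([0, 1], [0, 1]))
        self.grads["W"] = dW
        dyp = np.pad(dy, ((0, 0), (self.pad, self.pad), (0, 0)))
        dx = np.matmul(dyp[:, 0:L, :], W[self.kernel - 1].T)
        for j in range(1, self.kernel):
            dx += np.matmul(dyp[:, j:j + L, :], W[self.kernel - 1 - j].T)
        return dx


class Conv2d(Layer):
    """Stride-1 same-padded square 2D convolution on (N, H, W, C) tensors."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel must be odd, got {kernel}")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = kernel // 2
        self.params = {
            "W": _he_init(rng, (kernel, kernel, in_ch, out_ch),
                          in_ch * kernel * kernel, dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }

    def forward(self, x, training=False):
        W = self.params["W"]
        k, p = self.kernel, self.pad
        H, Wd = x.shape[1], x.shape[2]
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp, self._hw = xp, (H, Wd)
        y = None
        for i in range(k):
            for j in range(k):
                term = np.matmul(xp[:, i:i + H, j:j + Wd, :], W[i, j])
                y = term if y is None else y + term
        return y + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        k = self.kernel
        xp, (H, Wd) = self._xp, self._hw
        self.grads["b"] = dy.sum(axis=(0, 1, 2))
        dW = np.empty_like(W)
        for i in range(k):
            for j in range(k):
                dW[i, j] = np.tensordot(xp[:, i:i + H, j:j + Wd, :], dy,
                                        axes=([0, 1, 2], [0, 1, 2]))
        self.grads["W"] = dW
        p = self.pad
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (0, 0)))
        dx = None
        for i in range(k):
            for j in range(k):
                term = np.matmul(dyp[:, i:i + H, j:j + Wd, :],
                                 W[k - 1 - i, k - 1 - j].T)
                dx = term if dx is None else dx + term
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes except the trailing channel axis."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params = {
            "gamma": np.ones(n_ch, dtype=dtype),
            "beta": np.zeros(n_ch, dtype=dtype),
        }
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean.astype(np.float64)
            self.running_var = m * self.running_var + (1 - m) * var.astype(np.float64)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv
        self._xhat, self._inv, self._axes = xhat, inv, axes
        self._training = training
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        axes = self._axes
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        if not self._training:
            return dxhat * inv
        n = dy.size // dy.shape[-1]
        term = dxhat - dxhat.mean(axis=axes, keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / n
        return term * inv


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool1d(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        N, L, C = x.shape
        Lc = (L // s) * s
        self._in_len = L
        return x[:, :Lc, :].reshape(N, Lc // s, s, C).mean(axis=2)

    def backward(self, dy):
        s = self.size
        dx = np.repeat(dy, s, axis=1) / s
        pad = self._in_len - dx.shape[1]
        if pad:
            dx = np.pad(dx, ((0, 0), (0, pad), (0, 0)))
        return dx


class MaxPool1d(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, training=False):
        s = self.size
        N, L, C = x.shape
        Lc = (L // s) * s
        self._in_len = L
        xr = x[:, :Lc, :].reshape(N, Lc // s, s, C)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        s = self.size
        N, Lp, C = dy.shape
        dx = np.zeros((N, Lp, s, C), dtype=dy.dtype)
        n, l, c = np.ogrid[:N, :Lp, :C]
        dx[n, l, self._arg, c] = dy
        dx = dx.reshape(N, Lp * s, C)
        pad = self._in_len - dx.shape[1]
        if pad:
            dx = np.pad(dx, ((0, 0), (0, pad), (0, 0)))
        return dx


class AvgPool2d(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, training=False):
        N, H, W, C = x.shape
        # an axis already reduced to < size stays unpooled
        sh = self.size if H >= self.size else 1
        sw = self.size if W >= self.size else 1
        Hc, Wc = (H // sh) * sh, (W // sw) * sw
        self._in_shape, self._s = (H, W), (sh, sw)
        xr = x[:, :Hc, :Wc, :].reshape(N, Hc // sh, sh, Wc // sw, sw, C)
        return xr.mean(axis=(2, 4))

    def backward(self, dy):
        sh, sw = self._s
        dx = np.repeat(np.repeat(dy, sh, axis=1), sw, axis=2) / (sh * sw)
        H, W = self._in_shape
        ph, pw = H - dx.shape[1], W - dx.shape[2]
        if ph or pw:
            dx = np.pad(dx, ((0, 0), (0, ph), (0, pw), (0, 0)))
        return dx


class GlobalAvgPool(Layer):
    """Mean over all middle axes: (N, ..., C) -> (N, C)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=tuple(range(1, x.ndim - 1)))

    def backward(self, dy):
        shape = self._shape
        n_el = int(np.prod(shape[1:-1]))
        dx = np.broadcast_to(
            dy.reshape((shape[0],) + (1,) * (len(shape) - 2) + (shape[-1],)), shape)
        return (dx / n_el).astype(dy.dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.params = {
            "W": _he_init(rng, (n_in, n_out), n_in, dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask
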