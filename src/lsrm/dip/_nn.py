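"""Minimal NumPy CNN building blocks with hand-written backpropagation.

Tensors are ``(channels, height, width)`` single images.  Only the pieces
needed for the encoder-decoder prior are implemented: strided 3x3/1x1
convolution (zero padding), leaky ReLU, nearest-neighbour 2x upsampling,
sigmoid, and an Adam optimizer.  Everything is deterministic given the
seeded generator used at construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "InstanceNorm", "LeakyReLU", "Upsample2", "Sigmoid", "Adam"]


class Conv2d:
    """2D convolution via im2col.  Zero padding of k//2 keeps spatial size
    at stride 1 and halves it at stride 2 (even inputs)."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 kernel: int = 3, stride: int = 1) -> None:
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))  # He init
        self.weight = rng.normal(0.0, scale, (c_out, c_in, kernel, kernel))
        self.bias = np.zeros(c_out)
        self.kernel = kernel
        self.stride = stride
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cache: tuple | None = None

    @property
    def parameters(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [self.grad_weight, self.grad_bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        p = k // 2
        c_in, h, w = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        ho, wo = win.shape[1], win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(
            c_in * k * k, ho * wo
        )
        c_out = self.weight.shape[0]
        y = self.weight.reshape(c_out, -1) @ cols
        y = y.reshape(c_out, ho, wo) + self.bias[:, None, None]
        self._cache = (cols, xp.shape, (h, w), (ho, wo))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "forward must run before backward"
        cols, xp_shape, (h, w), (ho, wo) = self._cache
        k, s = self.kernel, self.stride
        p = k // 2
        c_out = self.weight.shape[0]
        c_in = xp_shape[0]
        dy_mat = dy.reshape(c_out, -1)
        self.grad_weight[...] = (dy_mat @ cols.T).reshape(self.weight.shape)
        self.grad_bias[...] = dy.sum(axis=(1, 2))
        dcols = (self.weight.reshape(c_out, -1).T @ dy_mat).reshape(
            c_in, k, k, ho, wo
        )
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, i, j]
        return dxp[:, p : p + h, p : p + w] if p else dxp


class InstanceNorm:
    """Per-channel normalization over the spatial axes with learnable affine
    parameters; keeps activation magnitudes bounded so the sigmoid head
    cannot saturate early in the optimization."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.eps = eps
        self.grad_gamma = np.zeros_like(self.gamma)
        self.grad_beta = np.zeros_like(self.beta)
        self._cache: tuple | None = None

    @property
    def parameters(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [self.grad_gamma, self.grad_beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.grad_gamma[...] = (dy * xhat).sum(axis=(1, 2))
        self.grad_beta[...] = dy.sum(axis=(1, 2))
        g = dy * self.gamma[:, None, None]
        m1 = g.mean(axis=(1, 2), keepdims=True)
        m2 = (g * xhat).mean(axis=(1, 2), keepdims=True)
        return inv_std * (g - m1 - xhat * m2)


class LeakyReLU:
    def __init__(self, alpha: float = 0.1) -> None:
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward sums 2x2 blocks."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h2, w2 = dy.shape
        return dy.reshape(c, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4))


class Sigmoid:
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._out * (1.0 - self._out)


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
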