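"""Minimal 1-D convolutional network primitives (NumPy, manual backprop).

Implements exactly what the windowed denoiser needs: strided Conv1d,
ConvTranspose1d, ReLU and the Adam optimizer, with im2col/col2im-based
forward and backward passes.  Weight layout follows the common convention:
Conv1d weight is (out_channels, in_channels, k); ConvTranspose1d weight is
(in_channels, out_channels, k).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "ConvTranspose1d", "ReLU", "Adam", "Sequential"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, L) -> (N, C, L_out, k) patch view (copy)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    n, c, lp = x.shape
    l_out = (lp - k) // stride + 1
    s0, s1, s2 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, l_out, k), strides=(s0, s1, s2 * stride, s2)
    )
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, l_buffer: int, stride: int) -> np.ndarray:
    """Scatter-add (N, C, L_in, k) patches into a (N, C, l_buffer) buffer
    at positions ``stride * i + j``."""
    n, c, l_in, k = cols.shape
    out = np.zeros((n, c, l_buffer), dtype=cols.dtype)
    for j in range(k):
        out[:, :, j: j + stride * l_in: stride] += cols[:, :, :, j]
    return out


class Conv1d:
    """Strided 1-D convolution with 'same-ish' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, padding: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.W = rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel_size))
        self.b = rng.uniform(-bound, bound, size=out_channels)
        self.stride, self.padding = stride, padding
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def out_length(self, l_in: int) -> int:
        return (l_in + 2 * self.padding - self.W.shape[2]) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols = _im2col(x, self.W.shape[2], self.stride, self.padding)
        y = np.einsum("qck,nclk->nql", self.W, cols, optimize=True) + self.b[:, None]
        if train:
            self._cache = (x.shape, cols)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache  # type: ignore[misc]
        self.gW += np.einsum("nql,nclk->qck", dy, cols, optimize=True)
        self.gb += dy.sum(axis=(0, 2))
        dcols = np.einsum("nql,qck->nclk", dy, self.W, optimize=True)
        l_pad = x_shape[2] + 2 * self.padding
        dxp = _col2im(dcols, l_pad, self.stride)
        return dxp[:, :, self.padding: self.padding + x_shape[2]] if self.padding else dxp

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ConvTranspose1d:
    """Strided transposed 1-D convolution (fractionally-strided upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, padding: int, output_padding: int,
                 rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.W = rng.uniform(-bound, bound, size=(in_channels, out_channels, kernel_size))
        self.b = rng.uniform(-bound, bound, size=out_channels)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def out_length(self, l_in: int) -> int:
        k = self.W.shape[2]
        return (l_in - 1) * self.stride - 2 * self.padding + k + self.output_padding

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, l_in = x.shape
        k = self.W.shape[2]
        l_out = self.out_length(l_in)
        buf_len = (l_in - 1) * self.stride + k + self.output_padding
        cols = np.einsum("nci,cqk->nqik", x, self.W, optimize=True)
        buf = _col2im(cols, buf_len, self.stride)
        y = buf[:, :, self.padding: self.padding + l_out] + self.b[:, None]
        if train:
            self._cache = (x, l_in, buf_len, l_out)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, l_in, buf_len, l_out = self._cache  # type: ignore[misc]
        k = self.W.shape[2]
        dbuf = np.zeros((dy.shape[0], dy.shape[1], buf_len), dtype=dy.dtype)
        dbuf[:, :, self.padding: self.padding + l_out] = dy
        # gather the same patches the forward scattered into
        s0, s1, s2 = dbuf.strides
        dcols = np.lib.stride_tricks.as_strided(
            dbuf, shape=(dy.shape[0], dy.shape[1], l_in, k),
            strides=(s0, s1, s2 * self.stride, s2),
        )
        self.gW += np.einsum("nci,nqik->cqk", x, dcols, optimize=True)
        self.gb += dy.sum(axis=(0, 2))
        return np.einsum("nqik,cqk->nci", dcols, self.W, optimize=True)

    @property
    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    @property
    def params(self):
        return []


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[:] = 0.0

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
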