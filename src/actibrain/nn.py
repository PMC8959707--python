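"""Minimal 1-D convolutional neural-network primitives in numpy (float64, CPU).

Implements exactly what the activity autoencoder needs: strided Conv1d,
ConvTranspose1d, ReLU and an Adam optimizer.  Convolution is the standard
cross-correlation with zero padding:

    out[n, o, t] = b[o] + sum_{c, j} W[o, c, j] * x_pad[n, c, t*stride + j]

ConvTranspose1d is its exact adjoint (same geometry parameters plus an
``output_padding`` to disambiguate output length), so the two share the
im2col/col2im machinery.  All layers carry analytic gradients that are
verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "ConvTranspose1d", "ReLU", "Adam", "conv_output_length",
           "conv_transpose_output_length"]


def conv_output_length(length: int, kernel: int, stride: int, padding: int) -> int:
    return (length + 2 * padding - kernel) // stride + 1


def conv_transpose_output_length(
    length: int, kernel: int, stride: int, padding: int, output_padding: int
) -> int:
    return (length - 1) * stride - 2 * padding + kernel + output_padding


def _gather(xp: np.ndarray, kernel: int, stride: int, n_out: int) -> np.ndarray:
    """View of a padded (N, C, L) array as (N, C, n_out, kernel) patches."""
    s0, s1, s2 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(xp.shape[0], xp.shape[1], n_out, kernel),
        strides=(s0, s1, s2 * stride, s2),
        writeable=False,
    )


def _scatter_add(target: np.ndarray, patches: np.ndarray, stride: int) -> None:
    """Adjoint of :func:`_gather`: accumulate (N, C, n_out, k) into (N, C, L)."""
    n_out, kernel = patches.shape[2], patches.shape[3]
    for j in range(kernel):
        target[:, :, j : j + (n_out - 1) * stride + 1 : stride] += patches[:, :, :, j]


class Conv1d:
    """Strided 1-D convolution with zero padding and He-initialized weights."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size))
        self.bias = np.zeros(out_channels)
        self.stride = stride
        self.padding = padding
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.weight.shape[2]
        n_out = conv_output_length(x.shape[2], k, self.stride, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        cols = _gather(xp, k, self.stride, n_out)
        out = np.einsum("ocj,nctj->not", self.weight, cols, optimize=True)
        out += self.bias[None, :, None]
        self._cache = (x.shape, xp, cols)
        return out

    def backward(self, grad_out: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        x_shape, xp, cols = self._cache
        grad_w = np.einsum("not,nctj->ocj", grad_out, cols, optimize=True)
        grad_b = grad_out.sum(axis=(0, 2))
        patches = np.einsum("ocj,not->nctj", self.weight, grad_out, optimize=True)
        grad_xp = np.zeros_like(xp)
        _scatter_add(grad_xp, patches, self.stride)
        p = self.padding
        grad_x = grad_xp[:, :, p : p + x_shape[2]]
        return grad_x, [grad_w, grad_b]


class ConvTranspose1d:
    """Transposed (fractionally strided) 1-D convolution, adjoint of Conv1d."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        output_padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_channels, out_channels, kernel_size))
        self.bias = np.zeros(out_channels)
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _, l_in = x.shape
        k = self.weight.shape[2]
        full = (l_in - 1) * self.stride + k + self.output_padding
        out_len = full - 2 * self.padding
        y_full = np.zeros((n, self.weight.shape[1], full))
        patches = np.einsum("coj,nct->notj", self.weight, x, optimize=True)
        _scatter_add(y_full, patches, self.stride)
        p = self.padding
        y = y_full[:, :, p : p + out_len].copy()
        y += self.bias[None, :, None]
        self._cache = (x, full)
        return y

    def backward(self, grad_out: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        x, full = self._cache
        k = self.weight.shape[2]
        p = self.padding
        grad_full = np.zeros((grad_out.shape[0], grad_out.shape[1], full))
        grad_full[:, :, p : p + grad_out.shape[2]] = grad_out
        cols = _gather(grad_full, k, self.stride, x.shape[2])  # (N, O, L_in, k)
        grad_x = np.einsum("coj,notj->nct", self.weight, cols, optimize=True)
        grad_w = np.einsum("nct,notj->coj", x, cols, optimize=True)
        grad_b = grad_out.sum(axis=(0, 2))
        return grad_x, [grad_w, grad_b]


class ReLU:
    """Elementwise max(x, 0); parameter-free."""

    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        return grad_out * self._mask, []


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
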