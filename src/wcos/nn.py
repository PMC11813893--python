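"""Minimal 1-D convolutional network layers with explicit backpropagation.

Internal building blocks for the convolutional autoencoder: strided Conv1d,
ConvTranspose1d (with output-padding so encoder lengths invert exactly),
BatchNorm1d with running statistics, LeakyReLU/ReLU/Tanh, an L1 loss and Adam.
Everything is plain numpy (float64) and fully deterministic given a seed.

Array convention: activations are (batch, channels, length). Parameters and
activations use ``DTYPE`` (float32 by default: conv autoencoders gain nothing
from double precision and the memory bandwidth halves).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Strided 1-D convolution (cross-correlation), symmetric zero padding."""

    def __init__(self, in_ch, out_ch, kernel, stride, padding, rng):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        bound = 1.0 / np.sqrt(in_ch * kernel)  # torch-style uniform fan-in init
        self.W = rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel)).astype(DTYPE)
        self.b = rng.uniform(-bound, bound, size=out_ch).astype(DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def out_len(self, L: int) -> int:
        n = L + 2 * self.p - self.k
        if n < 0:
            raise ValueError(
                f"input length {L} too short for kernel {self.k} with padding "
                f"{self.p}; pad the input by at least {-n} samples"
            )
        return n // self.s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p)))
        Lout = self.out_len(x.shape[2])
        view = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.s][:, :, :Lout]
        self._view, self._in_len = view, x.shape[2]
        return np.einsum("bclk,ock->bol", view, self.W, optimize=True) + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gW += np.einsum("bol,bclk->ock", gy, self._view, optimize=True)
        self.gb += gy.sum(axis=(0, 2))
        B, _, Lout = gy.shape
        gxp = np.zeros((B, self.in_ch, self._in_len + 2 * self.p), dtype=gy.dtype)
        for k in range(self.k):
            contrib = np.einsum("bol,oc->bcl", gy, self.W[:, :, k], optimize=True)
            gxp[:, :, k : k + self.s * Lout : self.s] += contrib
        return gxp[:, :, self.p : self.p + self._in_len]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class ConvTranspose1d(Layer):
    """Transposed strided convolution; ``output_padding`` appends zeros so the
    matching encoder layer's input length is restored exactly."""

    def __init__(self, in_ch, out_ch, kernel, stride, padding, output_padding, rng):
        if not 0 <= output_padding < stride:
            raise ValueError("output_padding must lie in [0, stride)")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p, self.op = kernel, stride, padding, output_padding
        bound = 1.0 / np.sqrt(in_ch * kernel)
        self.W = rng.uniform(-bound, bound, size=(in_ch, out_ch, kernel)).astype(DTYPE)
        self.b = rng.uniform(-bound, bound, size=out_ch).astype(DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def out_len(self, L: int) -> int:
        return (L - 1) * self.s + self.k - 2 * self.p + self.op

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, _, L = x.shape
        full = (L - 1) * self.s + self.k
        y = np.zeros((B, self.out_ch, full + self.op), dtype=x.dtype)
        for k in range(self.k):
            contrib = np.einsum("bcl,co->bol", x, self.W[:, :, k], optimize=True)
            y[:, :, k : k + self.s * L : self.s] += contrib
        self._x = x
        Lout = self.out_len(L)
        y = y[:, :, self.p : self.p + Lout]
        return y + self.b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gb += gy.sum(axis=(0, 2))
        L = self._x.shape[2]
        # re-embed the cropped gradient into the full (pre-padding) grid
        full = (L - 1) * self.s + self.k + self.op
        gfull = np.zeros((gy.shape[0], self.out_ch, full), dtype=gy.dtype)
        gfull[:, :, self.p : self.p + gy.shape[2]] = gy
        view = sliding_window_view(gfull, self.k, axis=2)[:, :, :: self.s][:, :, :L]
        self.gW += np.einsum("bcl,bolk->cok", self._x, view, optimize=True)
        return np.einsum("bolk,cok->bcl", view, self.W, optimize=True)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class BatchNorm1d(Layer):
    def __init__(self, ch, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(ch, dtype=DTYPE)
        self.beta = np.zeros(ch, dtype=DTYPE)
        self.ggamma = np.zeros(ch, dtype=DTYPE)
        self.gbeta = np.zeros(ch, dtype=DTYPE)
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, L = gy.shape
        n = B * L
        self.ggamma += (gy * self._xhat).sum(axis=(0, 2))
        self.gbeta += gy.sum(axis=(0, 2))
        gxhat = gy * self.gamma[None, :, None]
        if not self.training:
            return gxhat / self._std[None, :, None]
        m1 = gxhat.sum(axis=(0, 2)) / n
        m2 = (gxhat * self._xhat).sum(axis=(0, 2)) / n
        return (gxhat - m1[None, :, None] - self._xhat * m2[None, :, None]) / self._std[
            None, :, None
        ]

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y**2)


def l1_loss(x: np.ndarray, xhat: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-element mean absolute error and its gradient w.r.t. ``xhat``."""
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    diff = xhat - x
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad


class Adam:
    def __init__(self, params: list[np.ndarray], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    @staticmethod
    def zero_grads(grads: list[np.ndarray]) -> None:
        for g in grads:
            g[...] = 0.0
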