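"""A small, fully seeded numpy engine for 1-D convolutional networks.

Layers implement explicit ``forward``/``backward`` passes; gradients are
exact (verified against finite differences in the test suite).  Convolution
is computed by gathering dilated tap columns and contracting them with a
single GEMM, which keeps 15-block networks tractable on one CPU core.

Everything is deterministic given the ``numpy.random.Generator`` handed to
the constructors: two builds from the same seed produce bit-identical
initial weights, and training loops that seed their shuffling reproduce
bit-identical histories.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: layers cache what backward needs during forward."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []


def _same_padding(length: int, span: int, stride: int) -> tuple[int, int, int]:
    """(pad_left, pad_right, out_length) for 'same' conv semantics."""
    out_len = -(-length // stride)  # ceil
    total = max((out_len - 1) * stride + span - length, 0)
    left = total // 2
    return left, total - left, out_len


class Conv1d(Layer):
    """Dilated 1-D convolution over (batch, channels, length) arrays.

    ``dilation`` is the tap stride (>= 1); ``padding`` is ``"same"`` (zero
    padding, output length ``ceil(L / stride)``) or ``"valid"`` (no padding;
    inputs shorter than the kernel span raise).  Weights use He (fan-in)
    initialization; biases start at zero.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        dilation: int = 1,
        padding: str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        if dilation < 1:
            raise ValueError("dilation (tap stride) must be >= 1; map d=0 to 1 upstream")
        rng = rng if rng is not None else np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.padding = padding
        self.span = (kernel_size - 1) * dilation + 1
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(in_channels * kernel_size, out_channels))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _tap_slice(self, xp: np.ndarray, i: int, L_out: int) -> np.ndarray:
        start = i * self.dilation
        return xp[:, :, start : start + (L_out - 1) * self.stride + 1 : self.stride]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, C, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        if self.padding == "same":
            pl, pr, L_out = _same_padding(L, self.span, self.stride)
            xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        else:
            if L < self.span:
                raise ValueError(
                    f"input length {L} is shorter than the kernel span {self.span} "
                    f"and padding is disabled"
                )
            pl = 0
            L_out = (L - self.span) // self.stride + 1
            xp = x
        # one GEMM per kernel tap: y[b,f,t] = sum_i W_i^T @ xp[b,:,t*s + i*d]
        Wr = self.weight.value.reshape(C, self.kernel_size, self.out_channels)
        y = np.zeros((B, self.out_channels, L_out), dtype=x.dtype)
        for i in range(self.kernel_size):
            y += np.matmul(Wr[:, i, :].T[None], self._tap_slice(xp, i, L_out))
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        if training:
            self._cache = (xp, pl, L, L_out)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, pl, L, L_out = self._cache
        C, k, F = self.in_channels, self.kernel_size, self.out_channels
        Wr = self.weight.value.reshape(C, k, F)
        dWr = self.weight.grad.reshape(C, k, F)
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (B, L_out, F)
        dxp = np.zeros(xp.shape, dtype=dy.dtype)
        for i in range(k):
            sl = self._tap_slice(xp, i, L_out)             # (B, C, L_out)
            dWr[:, i, :] += np.matmul(sl, dyt).sum(axis=0)
            self._tap_slice(dxp, i, L_out)[...] += np.matmul(Wr[:, i, :][None], dy)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
        self._cache = None
        return dxp[:, :, pl : pl + L] if (xp.shape[2] != L) else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        y = self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]
        if training:
            self._cache = (xhat, inv_std)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        B, C, L = dy.shape
        n = B * L
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n
        ) * inv_std[None, :, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0)
        self._mask = None
        return dx


class GlobalAvgPool(Layer):
    """Mean over the temporal axis: (B, C, L) -> (B, C)."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        return np.repeat(dy[:, :, None], L, axis=2) / L


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng()
        w = rng.normal(0.0, math.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))
        self._x = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value.T
        self._x = None
        return dx


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    B = logits.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(B), labels], 1e-12))
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return float(nll.mean()), (dlogits / B).astype(logits.dtype)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def parameter_count(layers_or_params: Iterable) -> int:
    """Total trainable scalars across layers (or a flat Param iterable)."""
    total = 0
    for item in layers_or_params:
        if isinstance(item, Param):
            total += item.size
        else:
            total += sum(p.size for p in item.parameters())
    return total
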