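"""Minimal NumPy layer library with hand-written backpropagation.

Everything the counting networks need — grouped 2-D convolution (im2col +
BLAS matmul), batch normalization, ReLU/sigmoid, and momentum SGD — on
single images laid out as ``(C, H, W)`` float32 arrays. Batch size is 1
throughout, matching how the counting networks are trained, so no batch axis
is carried.

Layers cache what their backward pass needs during ``forward(train=True)``;
``backward`` consumes the cache and accumulates parameter gradients in
``Param.grad``.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

__all__ = [
    "Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid", "SGD",
]

_F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Grouped 2-D convolution with 'same' padding for odd kernels.

    Output spatial size is ``ceil(H / stride)``. ``pad_mode`` is ``"zeros"``
    or ``"circular"`` (periodic; used for translation-equivariance checks).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 groups: int = 1, bias: bool = True, pad_mode: str = "zeros",
                 rng: np.random.Generator | None = None) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if in_ch % groups or out_ch % groups:
            raise ValueError(
                f"groups={groups} must divide in_ch={in_ch} and out_ch={out_ch}"
            )
        if pad_mode not in ("zeros", "circular"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.groups, self.pad_mode = stride, groups, pad_mode
        rng = rng or np.random.default_rng()
        fan_in = (in_ch // groups) * kernel * kernel
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch // groups, kernel, kernel))
        self.weight = Param(w, "conv.weight")
        self.bias = Param(np.zeros(out_ch), "conv.bias") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        if p == 0:
            return x
        mode = "constant" if self.pad_mode == "zeros" else "wrap"
        return np.pad(x, ((0, 0), (p, p), (p, p)), mode=mode)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, g = self.kernel, self.stride, self.groups
        xp = self._pad(np.ascontiguousarray(x, dtype=_F32))
        ho, wo = -(-h // s), -(-w // s)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (C, ho, wo, k, k)
        cols = win.transpose(0, 3, 4, 1, 2).reshape(c, k * k, ho * wo)
        cg, og = c // g, self.out_ch // g
        out = np.empty((self.out_ch, ho * wo), dtype=_F32)
        wmat = self.weight.value.reshape(g, og, cg * k * k)
        cols_g = cols.reshape(g, cg * k * k, ho * wo)
        for gi in range(g):
            np.matmul(wmat[gi], cols_g[gi], out=out[gi * og:(gi + 1) * og])
        if self.bias is not None:
            out += self.bias.value[:, None]
        if train:
            self._cache = (cols_g, (c, h, w), (ho, wo))
        return out.reshape(self.out_ch, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward(train=True)")
        cols_g, (c, h, w), (ho, wo) = self._cache
        k, s, g = self.kernel, self.stride, self.groups
        cg, og = c // g, self.out_ch // g
        gout2 = np.ascontiguousarray(gout, dtype=_F32).reshape(self.out_ch, ho * wo)
        if self.bias is not None:
            self.bias.grad += gout2.sum(axis=1)
        wmat = self.weight.value.reshape(g, og, cg * k * k)
        gw = self.weight.grad.reshape(g, og, cg * k * k)
        gcols = np.empty((g, cg * k * k, ho * wo), dtype=_F32)
        for gi in range(g):
            go = gout2[gi * og:(gi + 1) * og]
            gw[gi] += go @ cols_g[gi].transpose()
            np.matmul(wmat[gi].T, go, out=gcols[gi])
        # scatter columns back onto the (padded) input grid
        p = k // 2
        hp, wp = h + 2 * p, w + 2 * p
        gxp = np.zeros((c, hp, wp), dtype=_F32)
        gcols = gcols.reshape(c, k, k, ho, wo)
        for a in range(k):
            for b in range(k):
                gxp[:, a:a + s * ho:s, b:b + s * wo:s] += gcols[:, a, b]
        if p == 0:
            gx = gxp
        elif self.pad_mode == "zeros":
            gx = gxp[:, p:p + h, p:p + w]
        else:  # circular: fold the wrapped borders back
            gx = gxp[:, p:p + h, p:p + w].copy()
            gx[:, :p, :] += gxp[:, p + h:, p:p + w]
            gx[:, h - p:, :] += gxp[:, :p, p:p + w]
            tmp = gxp[:, p:p + h, :p]
            gx[:, :, :p] += gxp[:, p:p + h, p + w:]
            gx[:, :, w - p:] += tmp
            # corners wrap through both axes; handled by the row folds above
            gx[:, :p, :p] += gxp[:, p + h:, p + w:]
            gx[:, :p, w - p:] += gxp[:, p + h:, :p]
            gx[:, h - p:, :p] += gxp[:, :p, p + w:]
            gx[:, h - p:, w - p:] += gxp[:, :p, :p]
        self._cache = None
        return gx


class BatchNorm2d(Layer):
    """Per-channel normalization over the spatial axes (batch of one).

    Training uses the current image's statistics and updates running
    estimates; evaluation uses the stored running statistics, which makes
    eval-mode forward passes deterministic.
    """

    def __init__(self, ch: int, *, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(np.ones(ch), "bn.gamma")
        self.beta = Param(np.zeros(ch), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=_F32)
        self.running_var = np.ones(ch, dtype=_F32)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[0] != self.ch:
            raise ValueError(f"expected {self.ch} channels, got {x.shape[0]}")
        if train:
            mu = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            m = self.momentum
            self.running_mean += m * (mu - self.running_mean)
            self.running_var += m * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xn = (x - mu[:, None, None]) * inv[:, None, None]
        out = self.gamma.value[:, None, None] * xn + self.beta.value[:, None, None]
        if train:
            self._cache = (xn.astype(_F32), inv.astype(_F32))
        return out.astype(_F32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward(train=True)")
        xn, inv = self._cache
        nhw = xn.shape[1] * xn.shape[2]
        self.beta.grad += gout.sum(axis=(1, 2))
        self.gamma.grad += (gout * xn).sum(axis=(1, 2))
        gxn = gout * self.gamma.value[:, None, None]
        s1 = gxn.sum(axis=(1, 2), keepdims=True)
        s2 = (gxn * xn).sum(axis=(1, 2), keepdims=True)
        gx = (gxn - s1 / nhw - xn * s2 / nhw) * inv[:, None, None]
        self._cache = None
        return gx.astype(_F32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called before forward(train=True)")
        gx = gout * self._mask
        self._mask = None
        return gx


class Abs(Layer):
    """Absolute-value rectification: non-negative output, gradient everywhere.

    Used as the density head's clamp — a ReLU head can die globally when the
    count loss pushes the whole map toward zero, while ``|x|`` keeps the
    subgradient alive (sign(0) = 0 at the kink).
    """

    def __init__(self) -> None:
        self._sign: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._sign = np.sign(x)
        return np.abs(x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._sign is None:
            raise RuntimeError("backward called before forward(train=True)")
        gx = gout * self._sign
        self._sign = None
        return gx


class Sigmoid(Layer):
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x, dtype=_F32))
        if train:
            self._out = out
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._out is None:
            raise RuntimeError("backward called before forward(train=True)")
        gx = gout * self._out * (1.0 - self._out)
        self._out = None
        return gx


class SGD:
    """Stochastic gradient descent with optional classical momentum."""

    def __init__(self, params: Iterable[Param], lr: float,
                 momentum: float = 0.0) -> None:
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if self.momentum:
                v *= self.momentum
                v -= self.lr * p.grad
                p.value += v
            else:
                p.value -= self.lr * p.grad
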