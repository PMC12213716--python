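"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an ndarray and
records the operations producing it; ``backward()`` walks the tape in reverse
topological order.  Supported operations are exactly what the generator and
discriminator architectures in :mod:`fieldbridge.learned_sr` need — elementwise
arithmetic with broadcasting, matmul, 2-D convolution (via strided im2col),
pixel shuffle, pooling, activations, softmax/layer-norm building blocks and
reductions.  Everything runs in float64 on a single thread, so training is
bit-reproducible for a fixed seed and data order.
"""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: Tuple["Tensor", ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        topo: list[Tensor] = []
        seen = set()

        def build(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def back(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(self.data / other.data, (self, other), back)

    def __pow__(self, p: float):
        def back(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), back)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def back(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            og = np.swapaxes(self.data, -1, -2) @ g
            other._accum(_unbroadcast(og, other.shape))

        return self._make(self.data @ other.data, (self, other), back)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def back(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), back)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def back(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), back)

    def concat(self, other: "Tensor", axis: int = 1) -> "Tensor":
        other = self._lift(other)
        n = self.shape[axis]

        def back(g):
            g1, g2 = np.split(g, [n], axis=axis)
            self._accum(g1)
            other._accum(g2)

        return self._make(
            np.concatenate([self.data, other.data], axis=axis), (self, other), back
        )

    # -- activations & pointwise ------------------------------------------
    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0

        def back(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return self._make(np.where(mask, self.data, slope * self.data), (self,), back)

    def relu(self) -> "Tensor":
        return self.leaky_relu(0.0)

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def back(g):
            self._accum(g * (1 - y**2))

        return self._make(y, (self,), back)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            self._accum(g * y * (1 - y))

        return self._make(y, (self,), back)

    def exp(self) -> "Tensor":
        y = np.exp(self.data)

        def back(g):
            self._accum(g * y)

        return self._make(y, (self,), back)

    def log(self) -> "Tensor":
        def back(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), back)

    def abs(self) -> "Tensor":
        s = np.sign(self.data)

        def back(g):
            self._accum(g * s)

        return self._make(np.abs(self.data), (self,), back)

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.shape

        def back(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))

        return self._make(y, (self,), back)

    # -- structured ops ---------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution (cross-correlation) on (N, C, H, W) input with
        (O, C, kh, kw) weights."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError("channel mismatch in conv2d")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        # win: (N, C, Ho, Wo, kh, kw)
        out = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
        if bias is not None:
            out = out + bias.data[None, :, None, None]
        ho, wo = out.shape[2], out.shape[3]

        def back(g):
            weight._accum(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            gx = np.zeros_like(xp)
            # scatter-add each kernel tap's contribution
            for i in range(kh):
                for j in range(kw):
                    contrib = np.einsum("nohw,oc->nchw", g, w[:, :, i, j], optimize=True)
                    gx[:, :, i : i + ho * stride : stride,
                       j : j + wo * stride : stride] += contrib
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            self._accum(gx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out, parents, back)

    def pixel_shuffle(self, r: int) -> "Tensor":
        """(N, C·r², H, W) → (N, C, rH, rW), channel c·r² + i·r + j of input
        cell (h, w) landing at output pixel (h·r + i, w·r + j)."""
        n, cr2, h, w = self.shape
        if cr2 % (r * r) != 0:
            raise ValueError("channel count not divisible by r^2")
        c = cr2 // (r * r)
        y = (
            self.data.reshape(n, c, r, r, h, w)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, c, h * r, w * r)
        )

        def back(g):
            gx = (
                g.reshape(n, c, h, r, w, r)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(n, cr2, h, w)
            )
            self._accum(gx)

        return self._make(y, (self,), back)

    def avg_pool2(self) -> "Tensor":
        """2×2 average pooling with stride 2 on (N, C, H, W)."""
        n, c, h, w = self.shape
        y = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def back(g):
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
            self._accum(gx)

        return self._make(y, (self,), back)

    def upsample_nearest2(self) -> "Tensor":
        """Nearest-neighbor ×2 upsampling on (N, C, H, W)."""
        n, c, h, w = self.shape
        y = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)

        def back(g):
            gx = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            self._accum(gx)

        return self._make(y, (self,), back)


def stack_params(params: Iterable[Tensor]) -> int:
    return sum(int(np.prod(p.shape)) for p in params)
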