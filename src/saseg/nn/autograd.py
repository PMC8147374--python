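"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the segmentation networks need are implemented:
elementwise arithmetic with broadcasting, relu/sigmoid/log/clip,
reductions, 2D convolution (dense and depthwise), 2x2 max pooling,
nearest-neighbour upsampling, channel concatenation and batch
normalization.  Convolutions are evaluated as einsum contractions over
strided sliding-window views, so the heavy lifting stays inside BLAS.

Tensors are float32 throughout; gradients are accumulated in float32 as
well, which is ample for the shallow networks trained here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _make(self, data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep unrolled graphs must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free graph

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return self._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), bw)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes only through the unclipped region."""
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            self._accum(g * ((self.data >= lo) & (self.data <= hi)))

        return self._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self) -> "Tensor":
        out_data = np.asarray(self.data.sum())

        def bw(g):
            self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), bw)

    def mean(self) -> "Tensor":
        n = self.data.size
        out_data = np.asarray(self.data.mean())

        def bw(g):
            self._accum(np.broadcast_to(g / n, self.data.shape))

        return self._make(out_data, (self,), bw)

    # -- spatial ops (NCHW) ---------------------------------------------------
    def conv2d(self, w: "Tensor", stride: int = 1, pad=(1, 1, 1, 1)) -> "Tensor":
        """2D convolution, x:(N,C,H,W) * w:(O,C,kh,kw), asymmetric padding
        ``pad=(top, bottom, left, right)``."""
        pt, pb, pl, pr = pad
        xp = np.pad(self.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        kh, kw = w.data.shape[2:]
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (N,C,Ho,Wo,kh,kw)
        out_data = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)

        def bw(g):
            if w.requires_grad:
                w._accum(np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
            if self.requires_grad:
                dcols = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
                dxp = np.zeros_like(xp)
                Ho, Wo = g.shape[2], g.shape[3]
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dcols[
                            :, :, :, :, i, j
                        ]
                H, W = self.data.shape[2], self.data.shape[3]
                self._accum(dxp[:, :, pt : pt + H, pl : pl + W])

        return self._make(out_data, (self, w), bw)

    def dwconv2d(self, w: "Tensor") -> "Tensor":
        """Depthwise 3x3 convolution (per-channel), x:(N,C,H,W) * w:(C,3,3)."""
        xp = np.pad(self.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        out_data = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)

        def bw(g):
            if w.requires_grad:
                w._accum(np.einsum("nchw,nchwij->cij", g, win, optimize=True))
            if self.requires_grad:
                dcols = np.einsum("nchw,cij->nchwij", g, w.data, optimize=True)
                dxp = np.zeros_like(xp)
                Ho, Wo = g.shape[2], g.shape[3]
                for i in range(3):
                    for j in range(3):
                        dxp[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j]
                H, W = self.data.shape[2], self.data.shape[3]
                self._accum(dxp[:, :, 1 : 1 + H, 1 : 1 + W])

        return self._make(out_data, (self, w), bw)

    def maxpool2x2(self) -> "Tensor":
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
        blocks = self.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
            dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(dx.reshape(n, c, h, w))

        return self._make(out_data, (self,), bw)

    def upsample2x(self) -> "Tensor":
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def bw(g):
            n, c, h, w = self.data.shape
            self._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return self._make(out_data, (self,), bw)

    def batchnorm(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Per-channel batch normalization over (N, H, W) of an NCHW tensor.

        ``running_mean``/``running_var`` are updated in place in training
        mode and used as the statistics in evaluation mode.
        """
        axes = (0, 2, 3)
        cview = (1, -1, 1, 1)
        if training:
            mu = self.data.mean(axis=axes)
            var = self.data.var(axis=axes)
            running_mean += momentum * (mu - running_mean)
            running_var += momentum * (var - running_var)
        else:
            mu, var = running_mean, running_var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu.reshape(cview)) * inv.reshape(cview)
        out_data = gamma.data.reshape(cview) * xhat + beta.data.reshape(cview)

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gi = g * gamma.data.reshape(cview)
                if training:
                    m = self.data.shape[0] * self.data.shape[2] * self.data.shape[3]
                    t1 = gi - gi.mean(axis=axes).reshape(cview)
                    t2 = xhat * (gi * xhat).sum(axis=axes).reshape(cview) / m
                    self._accum(inv.reshape(cview) * (t1 - t2))
                else:
                    self._accum(gi * inv.reshape(cview))

        return self._make(out_data, (self, gamma, beta), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    probe = tensors[0]
    return probe._make(out_data, tuple(tensors), bw)
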