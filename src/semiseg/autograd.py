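"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a dynamic tape.  Calling :meth:`Tensor.backward` on a scalar result
walks the tape in reverse topological order and accumulates gradients into
every tensor created with ``requires_grad=True``.

Only the operations needed by the segmentation networks are provided:
elementwise arithmetic, ``exp``/``log``, ReLU, reductions, reshaping,
concatenation, slicing, matrix multiplication, 2-D convolution, and
nearest-neighbour upsampling.  Tensors hold float32 or float64 data
(network training uses float32, the loss/metric oracles float64) and
every operation is deterministic given its inputs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class _NoGrad:
    _depth = 0

    def __enter__(self):
        _NoGrad._depth += 1
        return self

    def __exit__(self, *exc):
        _NoGrad._depth -= 1
        return False

    @staticmethod
    def active() -> bool:
        return _NoGrad._depth > 0


def no_grad() -> _NoGrad:
    """Context manager suppressing tape construction (inference mode)."""
    return _NoGrad()


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad.active()
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad.active() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic ----------------------------------------------------------
    # python scalars take a fast path (weak dtype promotion: float32 tensors
    # stay float32); everything else is wrapped into a constant Tensor
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data + other, (self,), lambda g: (g,))
        other = as_tensor(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data * other, (self,), lambda g: (g * other,))
        other = as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._make(self.data / other, (self,), lambda g: (g / other,))
        other = as_tensor(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            return (g * e * self.data ** (e - 1),)

        return Tensor._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise functions -----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max_const(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max of the underlying data as a constant (no gradient); used for
        numerically stable softmax where the shift is gradient-free."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            return (g.reshape(orig),)

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros(self.shape, dtype=self.data.dtype)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- structured ops ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        return conv2d(self, weight, bias, stride=stride, padding=padding)

    def upsample2_nearest(self) -> "Tensor":
        """Nearest-neighbour spatial x2 upsampling of a (B, C, H, W) tensor."""
        b, c, h, w = self.shape
        out_data = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)

        def backward(g):
            return (g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)),)

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep UNet tapes overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


# ---------------------------------------------------------------------------
# 2-D convolution: numba direct kernels when available (about 4x faster on
# CPU than the im2col/col2im fallback, which is memory-copy bound)
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit

    @_njit(fastmath=True, cache=True)
    def _nb_conv_fwd(xp, w, stride):
        b, c, hp, wp = xp.shape
        o, _, kh, kw = w.shape
        ho = (hp - kh) // stride + 1
        wo = (wp - kw) // stride + 1
        out = np.zeros((b, o, ho, wo), dtype=xp.dtype)
        for bb in range(b):
            for oo in range(o):
                for cc in range(c):
                    for i in range(kh):
                        for j in range(kw):
                            wv = w[oo, cc, i, j]
                            for y in range(ho):
                                for x in range(wo):
                                    out[bb, oo, y, x] += wv * xp[bb, cc, y * stride + i,
                                                                 x * stride + j]
        return out

    @_njit(fastmath=True, cache=True)
    def _nb_conv_dx(g, w, hp, wp, stride):
        b, o, ho, wo = g.shape
        _, c, kh, kw = w.shape
        dxp = np.zeros((b, c, hp, wp), dtype=g.dtype)
        for bb in range(b):
            for oo in range(o):
                for cc in range(c):
                    for i in range(kh):
                        for j in range(kw):
                            wv = w[oo, cc, i, j]
                            for y in range(ho):
                                for x in range(wo):
                                    dxp[bb, cc, y * stride + i, x * stride + j] += (
                                        wv * g[bb, oo, y, x])
        return dxp

    @_njit(fastmath=True, cache=True)
    def _nb_conv_dw(xp, g, kh, kw, stride):
        b, c, hp, wp = xp.shape
        _, o, ho, wo = g.shape
        dw = np.zeros((o, c, kh, kw), dtype=g.dtype)
        for bb in range(b):
            for oo in range(o):
                for cc in range(c):
                    for i in range(kh):
                        for j in range(kw):
                            acc = 0.0
                            for y in range(ho):
                                for x in range(wo):
                                    acc += g[bb, oo, y, x] * xp[bb, cc, y * stride + i,
                                                                x * stride + j]
                            dw[oo, cc, i, j] += acc
        return dw

    # stride-1 specialisations: a compile-time unit stride lets LLVM
    # vectorise the inner loops (roughly 8x faster than the generic kernels)
    @_njit(fastmath=True, cache=True)
    def _nb_conv_fwd1(xp, w):
        b, c, hp, wp = xp.shape
        o, _, kh, kw = w.shape
        ho = hp - kh + 1
        wo = wp - kw + 1
        out = np.zeros((b, o, ho, wo), dtype=xp.dtype)
        for bb in range(b):
            for oo in range(o):
                for cc in range(c):
                    for i in range(kh):
                        for j in range(kw):
                            wv = w[oo, cc, i, j]
                            for y in range(ho):
                                for x in range(wo):
                                    out[bb, oo, y, x] += wv * xp[bb, cc, y + i, x + j]
        return out

    @_njit(fastmath=True, cache=True)
    def _nb_conv_dx1(g, w, hp, wp):
        b, o, ho, wo = g.shape
        _, c, kh, kw = w.shape
        dxp = np.zeros((b, c, hp, wp), dtype=g.dtype)
        for bb in range(b):
            for oo in range(o):
                for cc in range(c):
                    for i in range(kh):
                        for j in range(kw):
                            wv = w[oo, cc, i, j]
                            for y in range(ho):
                                for x in range(wo):
                                    dxp[bb, cc, y + i, x + j] += wv * g[bb, oo, y, x]
        return dxp

    @_njit(fastmath=True, cache=True)
    def _nb_conv_dw1(xp, g, kh, kw):
        b, c, hp, wp = xp.shape
        _, o, ho, wo = g.shape
        dw = np.zeros((o, c, kh, kw), dtype=g.dtype)
        for bb in range(b):
            for oo in range(o):
                for cc in range(c):
                    for i in range(kh):
                        for j in range(kw):
                            acc = 0.0
                            for y in range(ho):
                                for x in range(wo):
                                    acc += g[bb, oo, y, x] * xp[bb, cc, y + i, x + j]
                            dw[oo, cc, i, j] += acc
        return dw

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    b, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, padding: int):
    b, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    # channels-last accumulator keeps every add contiguous; transpose once
    cols = cols.reshape(b, ho, wo, c, kh, kw)
    out = np.zeros((b, hp, wp, c), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, i : i + stride * ho : stride, j : j + stride * wo : stride, :] += (
                cols[:, :, :, :, i, j]
            )
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of (B, Cin, H, W) with (Cout, Cin, kh, kw) weights."""
    x = as_tensor(x)
    weight = as_tensor(weight)
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {cin}")
    if _HAVE_NUMBA:
        return _conv2d_direct(x, weight, bias, stride, padding)
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T  # (B, Ho*Wo, Cout)
    b = x.shape[0]
    out = out.transpose(0, 2, 1).reshape(b, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(b, cout, ho * wo).transpose(0, 2, 1)  # (B, Ho*Wo, Cout)
        gw = np.tensordot(gmat, cols, axes=([0, 1], [0, 1]))  # (Cout, Cin*kh*kw)
        gw = gw.reshape(cout, cin, kh, kw)
        gcols = gmat @ wmat  # (B, Ho*Wo, Cin*kh*kw)
        gx = _col2im(gcols, x.shape, kh, kw, stride, padding)
        if bias is None:
            return gx, gw
        gb = g.sum(axis=(0, 2, 3))
        return gx, gw, gb

    return Tensor._make(out, parents, backward)


def _conv2d_direct(x: Tensor, weight: Tensor, bias: Tensor | None,
                   stride: int, padding: int) -> Tensor:
    cout, cin, kh, kw = weight.shape
    b = x.shape[0]
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = np.ascontiguousarray(x.data)
    if weight.data.dtype != xp.dtype:
        raise TypeError("conv2d: input and weight dtypes must match")
    if stride == 1:
        out = _nb_conv_fwd1(xp, weight.data)
    else:
        out = _nb_conv_fwd(xp, weight.data, stride)
    if bias is not None:
        out += bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g = np.ascontiguousarray(g)
        if stride == 1:
            gw = _nb_conv_dw1(xp, g, kh, kw)
            gxp = _nb_conv_dx1(g, weight.data, xp.shape[2], xp.shape[3])
        else:
            gw = _nb_conv_dw(xp, g, kh, kw, stride)
            gxp = _nb_conv_dx(g, weight.data, xp.shape[2], xp.shape[3], stride)
        gx = gxp[:, :, padding:-padding, padding:-padding] if padding else gxp
        if bias is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor._make(out, parents, backward)
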