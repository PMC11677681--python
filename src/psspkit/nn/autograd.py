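"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A ``Tensor`` wraps an ndarray and records the operations that produced
it; ``backward()`` walks the tape in reverse topological order.  Only
the primitives the sequence models need are provided: elementwise
arithmetic, matmul, reductions, slicing, concatenation, the standard
activations, and a 1-D (optionally per-sample, dilated) convolution.
Gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # ---------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return mul(tsum(self, axis=axis, keepdims=keepdims), 1.0 / float(n))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes or None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad = t.grad + g


# -------------------------------------------------------------- basics

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(go):
        _accum(a, _unbroadcast(go, a.data.shape))
        _accum(b, _unbroadcast(go, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(go):
        _accum(a, _unbroadcast(go * b.data, a.data.shape))
        _accum(b, _unbroadcast(go * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** exponent

    def backward(go):
        _accum(a, go * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward(go):
        _accum(a, _unbroadcast(go @ np.swapaxes(b.data, -1, -2), a.data.shape))
        _accum(b, _unbroadcast(np.swapaxes(a.data, -1, -2) @ go, b.data.shape))

    return _make(a.data @ b.data, (a, b), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)

    def backward(go):
        g = go
        if not keepdims and axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.data.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        _accum(a, np.broadcast_to(g, a.data.shape).copy()
               if np.ndim(g) else np.full_like(a.data, g))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def getitem(a, key) -> Tensor:
    a = as_tensor(a)

    def backward(go):
        g = np.zeros_like(a.data)
        np.add.at(g, key, go)
        _accum(a, g)

    return _make(a.data[key], (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape

    def backward(go):
        _accum(a, go.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)

    def backward(go):
        _accum(a, go.transpose(np.argsort(axes)) if axes else go.T)

    return _make(a.data.transpose(axes) if axes else a.data.T, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(go):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * go.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, go[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = as_tensor(t)
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else axis + t.data.ndim + 1, 1)
        expanded.append(reshape(t, tuple(shape)))
    return concat(expanded, axis=axis)


# --------------------------------------------------------- activations

def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(go):
        _accum(a, go * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(go):
        _accum(a, go / a.data)

    return _make(np.log(a.data), (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(go):
        _accum(a, go * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(go):
        _accum(a, go * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def leaky_relu(a, negative_slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    factor = np.where(a.data > 0, 1.0, negative_slope)

    def backward(go):
        _accum(a, go * factor)

    return _make(a.data * factor, (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant
    e = exp(a - shift)
    return e / tsum(e, axis=axis, keepdims=True)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    z = a - shift
    return z - log(tsum(exp(z), axis=axis, keepdims=True))


def gather_rows(a, idx: np.ndarray) -> Tensor:
    """Pick a[i, idx[i]] for each row i of a 2-D tensor."""
    a = as_tensor(a)
    rows = np.arange(a.data.shape[0])

    def backward(go):
        g = np.zeros_like(a.data)
        np.add.at(g, (rows, idx), go)
        _accum(a, g)

    return _make(a.data[rows, idx], (a,), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  mask: Optional[np.ndarray] = None) -> Tensor:
    """Mean negative log-likelihood over (optionally masked) positions.

    ``logits`` is (M, C); ``targets`` integer class ids (M,);
    ``mask`` optional 0/1 weights (M,).
    """
    ls = log_softmax(logits, axis=-1)
    picked = gather_rows(ls, np.asarray(targets, dtype=np.int64))
    if mask is None:
        return mul(tsum(picked), -1.0 / picked.data.size)
    mask = np.asarray(mask, dtype=np.float64)
    denom = float(mask.sum())
    if denom == 0:
        raise ValueError("cross_entropy: mask selects no positions")
    return mul(tsum(mul(picked, mask)), -1.0 / denom)


# -------------------------------------------------------------- conv1d

def _window_index(L_out: int, K: int, dilation: int) -> np.ndarray:
    return (np.arange(L_out)[:, None] + np.arange(K)[None, :] * dilation)


def conv1d(x: Tensor, w: Tensor, bias: Optional[Tensor] = None,
           dilation: int = 1, padding: str = "same") -> Tensor:
    """1-D convolution over (N, C_in, L) input.

    ``w`` is (C_out, C_in, K) for shared filters or (N, C_out, C_in, K)
    for per-sample filters.  ``padding``: "same" (symmetric; output
    length L, requires odd effective kernel) or "causal" (left pad, the
    output at t sees inputs <= t only).
    """
    x, w = as_tensor(x), as_tensor(w)
    per_sample = w.data.ndim == 4
    K = w.data.shape[-1]
    span = (K - 1) * dilation
    if padding == "same":
        left = span // 2
        right = span - left
    elif padding == "causal":
        left, right = span, 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    N, C_in, L = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (left, right)))
    idx = _window_index(L, K, dilation)
    windows = xp[:, :, idx]  # (N, C_in, L, K)
    if per_sample:
        out_data = np.einsum("nclk,nock->nol", windows, w.data, optimize=True)
    else:
        out_data = np.einsum("nclk,ock->nol", windows, w.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]

    def backward(go):
        if per_sample:
            gw = np.einsum("nol,nclk->nock", go, windows, optimize=True)
            gwin = np.einsum("nol,nock->nclk", go, w.data, optimize=True)
        else:
            gw = np.einsum("nol,nclk->ock", go, windows, optimize=True)
            gwin = np.einsum("nol,ock->nclk", go, w.data, optimize=True)
        _accum(w, gw)
        gxp = np.zeros_like(xp)
        np.add.at(gxp, (slice(None), slice(None), idx), gwin)
        _accum(x, gxp[:, :, left:left + L] if right == 0
               else gxp[:, :, left:gxp.shape[2] - right])
        if bias is not None:
            _accum(bias, go.sum(axis=(0, 2)))

    parents = (x, w) if bias is None else (x, w, bias)
    return _make(out_data, parents, backward)
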