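"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for transformer encoders: broadcast arithmetic,
batched matmul, reshape/transpose, reductions, softmax, GELU, layer-norm
building blocks, and two indexing ops (row gather and masked sequence
assembly) used by the masked autoencoder.  Everything is float64 and
single-threaded numpy, so runs are bit-reproducible for a fixed seed.
"""
from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "take_rows", "gather_tokens", "assemble_sequence",
           "broadcast_to", "slice_axis1"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = x * cdf

        def backward(g):
            if self.requires_grad:
                pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
                self._accum(g * (cdf + x * pdf))

        return self._make(out, (self,), backward)

    def softmax(self):
        """Softmax along the last axis (numerically stabilised)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            if self.requires_grad:
                self._accum(y * (g - (g * y).sum(axis=-1, keepdims=True)))

        return self._make(y, (self,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def broadcast_to(t: Tensor, shape: tuple) -> Tensor:
    def backward(g):
        if t.requires_grad:
            t._accum(_unbroadcast(g, t.data.shape))

    return Tensor._make(np.broadcast_to(t.data, shape).copy(), (t,), backward)


def slice_axis1(x: Tensor, lo: int, hi: int) -> Tensor:
    """``x[:, lo:hi]`` for a (B, T, ...) tensor."""

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, lo:hi] = g
            x._accum(gx)

    return Tensor._make(x.data[:, lo:hi], (x,), backward)


def take_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """``table[idx]`` for a (T, D) parameter table and integer index array."""
    idx = np.asarray(idx)

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, idx.reshape(-1), g.reshape(-1, g.shape[-1]))
            table._accum(gt)

    return Tensor._make(table.data[idx], (table,), backward)


def gather_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Per-sample token gather: x (B,T,D), idx (B,K) -> (B,K,D)."""
    idx = np.asarray(idx)
    b_idx = np.arange(x.data.shape[0])[:, None]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, (b_idx, idx), g)
            x._accum(gx)

    return Tensor._make(x.data[b_idx, idx], (x,), backward)


def assemble_sequence(
    visible: Tensor, mask_token: Tensor, visible_idx: np.ndarray, n_tokens: int
) -> Tensor:
    """Scatter visible latents into a full sequence, mask token elsewhere.

    visible (B,K,D), mask_token (D,), visible_idx (B,K) -> (B,n_tokens,D).
    """
    visible_idx = np.asarray(visible_idx)
    batch, _, dim = visible.data.shape
    b_idx = np.arange(batch)[:, None]
    out = np.broadcast_to(mask_token.data, (batch, n_tokens, dim)).copy()
    out[b_idx, visible_idx] = visible.data
    mask_count = np.zeros((batch, n_tokens), dtype=bool)
    mask_count[b_idx, visible_idx] = True  # True where visible

    def backward(g):
        if visible.requires_grad:
            visible._accum(g[b_idx, visible_idx])
        if mask_token.requires_grad:
            mask_token._accum(g[~mask_count].sum(axis=0))

    return Tensor._make(out, (visible, mask_token), backward)
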