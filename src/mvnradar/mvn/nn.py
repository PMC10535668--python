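"""Transformer building blocks and the Adam optimizer on top of the
autodiff engine.

Blocks are pre-norm ("norm-first") transformer encoder layers — multi-head
self-attention and a GELU feed-forward, each behind layer normalization
with a residual connection — followed by a final layer normalization at the
top of each stack, the arrangement used by ViT-family encoders.
"""
from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "MultiHeadSelfAttention",
           "FeedForward", "EncoderBlock", "TransformerStack", "Adam"]


class Parameter(Tensor):
    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name


class Module:
    """Tiny module base: children and parameters discovered by attribute scan."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in vars(self).values():
            out.extend(_collect(value))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def checksum(self) -> int:
        import hashlib

        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(np.ascontiguousarray(a).tobytes())
        return int.from_bytes(h.digest()[:8], "big")


def _collect(value) -> list[Parameter]:
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = ""):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, (n_in, n_out)), f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out), f"{name}.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, name: str = "", eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), f"{name}.beta")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return self.gamma * (centred * (var + self.eps) ** -0.5) + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator, name: str = ""):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng, f"{name}.qkv")
        self.proj = Linear(dim, dim, rng, f"{name}.proj")

    def __call__(self, x: Tensor) -> Tensor:
        batch, seq, dim = x.shape
        qkv = self.qkv(x).reshape(batch, seq, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, T, hd)
        qkv_flat = qkv.reshape(3 * batch, self.heads, seq, self.head_dim)
        q = _third(qkv_flat, 0, batch)
        k = _third(qkv_flat, 1, batch)
        v = _third(qkv_flat, 2, batch)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(batch, seq, dim)
        return self.proj(out)


def _third(qkv_flat: Tensor, which: int, batch: int) -> Tensor:
    """Select q, k, or v from the stacked (3B, H, T, hd) tensor."""
    lo, hi = which * batch, (which + 1) * batch

    def backward(g):
        if qkv_flat.requires_grad:
            gg = np.zeros_like(qkv_flat.data)
            gg[lo:hi] = g
            qkv_flat._accum(gg)

    return Tensor._make(qkv_flat.data[lo:hi], (qkv_flat,), backward)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator, name: str = ""):
        self.fc1 = Linear(dim, hidden, rng, f"{name}.fc1")
        self.fc2 = Linear(hidden, dim, rng, f"{name}.fc2")

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class EncoderBlock(Module):
    def __init__(self, dim: int, heads: int, ffn_dim: int, rng: np.random.Generator, name: str = ""):
        self.norm1 = LayerNorm(dim, f"{name}.norm1")
        self.attn = MultiHeadSelfAttention(dim, heads, rng, f"{name}.attn")
        self.norm2 = LayerNorm(dim, f"{name}.norm2")
        self.ffn = FeedForward(dim, ffn_dim, rng, f"{name}.ffn")

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ffn(self.norm2(x))


class TransformerStack(Module):
    """n_layers pre-norm encoder blocks + final layer normalization."""

    def __init__(self, n_layers: int, dim: int, heads: int, ffn_dim: int,
                 rng: np.random.Generator, name: str = ""):
        self.blocks = [
            EncoderBlock(dim, heads, ffn_dim, rng, f"{name}.block{i}") for i in range(n_layers)
        ]
        self.norm = LayerNorm(dim, f"{name}.norm")

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return self.norm(x)


class Adam:
    """Adam with the usual bias correction; no weight decay."""

    def __init__(self, params: list[Parameter], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
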