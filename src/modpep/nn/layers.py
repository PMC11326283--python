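"""Transformer encoder building blocks on the autodiff engine.

The encoder is BERT-shaped with post-layer normalization; positional
information enters exclusively by rotating query/key vectors (rotary
embeddings), so attention depends only on relative offsets and there is no
learned absolute-position table.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "RotaryCache",
    "MultiHeadSelfAttention",
    "FeedForward",
    "EncoderBlock",
]


class Module:
    """Parameter container with recursive named-parameter discovery."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]} ...")
        for name, param in params.items():
            if param.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            param.data = state[name].astype(param.data.dtype).copy()

    def state(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters().items()}


def _init(rng: np.random.Generator, shape, scale: float = 0.02) -> Tensor:
    return Tensor((rng.standard_normal(shape) * scale).astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = _init(rng, (n_in, n_out))
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.weight = _init(rng, (n_tokens, dim))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return ad.embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta)


class RotaryCache:
    """Precomputed cos/sin tables for rotary position embedding."""

    def __init__(self, head_dim: int, max_len: int, base: float = 10000.0):
        if head_dim % 2:
            raise ValueError("rotary embedding needs an even head dimension")
        inv_freq = base ** (-np.arange(0, head_dim, 2, dtype=np.float64) / head_dim)
        angles = np.outer(np.arange(max_len, dtype=np.float64), inv_freq)
        self.cos = np.cos(angles).astype(np.float32)  # (max_len, head_dim/2)
        self.sin = np.sin(angles).astype(np.float32)

    def tables(self, length: int) -> tuple[np.ndarray, np.ndarray]:
        return self.cos[:length], self.sin[:length]


def apply_rotary(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """Rotate interleaved (even, odd) channel pairs of (B, H, T, Dh) by the
    position-dependent angles."""
    even = x[..., 0::2]
    odd = x[..., 1::2]
    out_even = even * cos - odd * sin
    out_odd = even * sin + odd * cos
    return ad.stack([out_even, out_odd], axis=-1).reshape(x.shape)


class MultiHeadSelfAttention(Module):
    def __init__(self, hidden: int, heads: int, rng: np.random.Generator):
        if hidden % heads:
            raise ValueError("hidden size must be divisible by the head count")
        self.heads = heads
        self.head_dim = hidden // heads
        self.query = Linear(hidden, hidden, rng)
        self.key = Linear(hidden, hidden, rng)
        self.value = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, hidden, rng)

    def __call__(self, x: Tensor, attn_bias: np.ndarray, rope: tuple[np.ndarray, np.ndarray]) -> Tensor:
        b, t, h = x.shape
        cos, sin = rope

        def split_heads(v: Tensor) -> Tensor:
            return v.reshape(b, t, self.heads, self.head_dim).transpose(0, 2, 1, 3)

        q = apply_rotary(split_heads(self.query(x)), cos, sin)
        k = apply_rotary(split_heads(self.key(x)), cos, sin)
        v = split_heads(self.value(x))
        scores = q @ k.transpose(0, 1, 3, 2) * float(1.0 / np.sqrt(self.head_dim))
        scores = scores + Tensor(attn_bias)
        weights = ad.softmax(scores, axis=-1)
        context = (weights @ v).transpose(0, 2, 1, 3).reshape(b, t, h)
        return self.out(context)


class FeedForward(Module):
    def __init__(self, hidden: int, intermediate: int, rng: np.random.Generator):
        self.dense_in = Linear(hidden, intermediate, rng)
        self.dense_out = Linear(intermediate, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.dense_out(self.dense_in(x).gelu())


class EncoderBlock(Module):
    """Post-LN transformer block: LN(x + attn(x)), then LN(x + ffn(x))."""

    def __init__(self, hidden: int, heads: int, intermediate: int, rng: np.random.Generator):
        self.attention = MultiHeadSelfAttention(hidden, heads, rng)
        self.ffn = FeedForward(hidden, intermediate, rng)
        self.norm_attn = LayerNorm(hidden)
        self.norm_ffn = LayerNorm(hidden)

    def __call__(self, x, attn_bias, rope, p_drop=0.0, rng=None):
        attn = self.attention(x, attn_bias, rope)
        if p_drop > 0.0:
            attn = ad.dropout(attn, p_drop, rng)
        x = self.norm_attn(x + attn)
        ffn = self.ffn(x)
        if p_drop > 0.0:
            ffn = ad.dropout(ffn, p_drop, rng)
        return self.norm_ffn(x + ffn)
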