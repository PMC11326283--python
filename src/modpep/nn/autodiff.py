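"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just the operations a transformer encoder needs: broadcast arithmetic,
batched matmul, reshape/transpose/slicing/stack, reductions, embedding
lookup, row gather, softmax, layer normalization, GELU and fused
softmax-cross-entropy. Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward` over a topologically sorted graph.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from scipy.special import ndtr

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    previous = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = previous


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(value, dtype=None) -> "Tensor":
    if isinstance(value, Tensor):
        return value
    if dtype is not None and isinstance(value, (int, float)):
        # keep python scalars from promoting float32 arrays to float64
        return Tensor(np.asarray(value, dtype=dtype))
    return Tensor(np.asarray(value))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
            for parent in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accumulate(g)
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg

    # -- basic properties --------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __pow__(self, exponent: float):
        return Tensor._make(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        a, b = self.data, other.data

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(np.matmul(a, b), (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inverse),)
        )

    def __getitem__(self, key):
        # integer-array keys may repeat indices and need scatter-add; basic
        # slicing never overlaps, so in-place += is safe and much faster
        parts = key if isinstance(key, tuple) else (key,)
        fancy = any(isinstance(p, np.ndarray) or isinstance(p, list) for p in parts)

        def backward(g):
            out = np.zeros_like(self.data)
            if fancy:
                np.add.at(out, key, g)
            else:
                out[key] += g
            return (out,)

        return Tensor._make(self.data[key], (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data**2),))

    def gelu(self):
        """Exact GELU, x * Phi(x)."""
        x = self.data
        phi = ndtr(x)
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return Tensor._make((x * phi).astype(x.dtype), (self,), lambda g: (g * (phi + x * pdf),))


# -- free functions ---------------------------------------------------------


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in pieces)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)

    def backward(g):
        out = np.zeros_like(weight.data)
        np.add.at(out, ids, g)
        return (out,)

    return Tensor._make(weight.data[ids], (weight,), backward)


def index_select(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows along axis 0."""
    idx = np.asarray(idx)

    def backward(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor._make(t.data[idx], (t,), backward)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        inner = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - inner),)

    return Tensor._make(y, (t,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with learnable scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        d = x.data.shape[-1]
        dxhat = g * gamma.data
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        axes = tuple(range(g.ndim - 1))
        return dx.astype(x.data.dtype), (g * xhat).sum(axis=axes), g.sum(axis=axes)

    return Tensor._make((xhat * gamma.data + beta.data).astype(x.data.dtype), (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; a no-op when p == 0."""
    if p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)


def cross_entropy(logits: Tensor, targets: np.ndarray, reduction: str = "mean") -> Tensor:
    """Softmax cross-entropy between ``logits`` (N, V) and integer targets (N,)."""
    targets = np.asarray(targets)
    n = logits.data.shape[0]
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=-1))
    nll = logsumexp - shifted[np.arange(n), targets]
    if reduction == "mean":
        value, scale = nll.mean(), 1.0 / n
    elif reduction == "sum":
        value, scale = nll.sum(), 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    def backward(g):
        probs = np.exp(shifted - logsumexp[..., None])
        probs[np.arange(n), targets] -= 1.0
        return ((g * scale) * probs.astype(logits.data.dtype),)

    return Tensor._make(np.asarray(value, dtype=logits.data.dtype), (logits,), backward)
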