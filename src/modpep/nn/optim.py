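"""AdamW with optional linear warmup."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Decoupled weight-decay Adam over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        warmup_steps: int = 0,
        decay_steps: int = 0,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.warmup_steps = warmup_steps
        self.decay_steps = decay_steps
        self.step_count = 0
        self._m = {k: np.zeros_like(p.data, dtype=np.float32) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data, dtype=np.float32) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def current_lr(self) -> float:
        if self.warmup_steps and self.step_count <= self.warmup_steps:
            return self.lr * self.step_count / self.warmup_steps
        if self.decay_steps:
            progress = min(max(self.step_count - self.warmup_steps, 0) / self.decay_steps, 1.0)
            return self.lr * 0.5 * (1.0 + np.cos(np.pi * progress))
        return self.lr

    def step(self) -> None:
        self.step_count += 1
        lr = self.current_lr()
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self.step_count
        bias2 = 1.0 - b2**self.step_count
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases/norms
                update = update + self.weight_decay * p.data
            p.data = p.data - lr * update
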