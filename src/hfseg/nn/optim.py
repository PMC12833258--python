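"""AdamW with decoupled weight decay and a step learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class AdamW:
    """Decoupled-weight-decay Adam over an explicit parameter list.

    Only parameters with ``requires_grad=True`` may be handed to the
    optimizer; frozen weights are never touched.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.1):
        self.params: list[Tensor] = list(params)
        if any(not p.requires_grad for p in self.params):
            raise ValueError("AdamW received a frozen parameter")
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def step_decay_lr(base_lr: float, epoch: int, drop_every: int = 20,
                  factor: float = 0.1) -> float:
    """Learning rate multiplied by `factor` every `drop_every` epochs."""
    return base_lr * factor ** (epoch // drop_every)
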