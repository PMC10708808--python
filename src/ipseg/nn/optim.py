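"""SGD with momentum and a step-decay learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["SGD", "step_decay_lr"]


def step_decay_lr(base_lr: float, epoch: int, interval: int, factor: float) -> float:
    """Learning rate after equal-interval reduction: lr * factor**(epoch//interval)."""
    if interval < 1:
        raise ValueError("decay interval must be >= 1")
    return base_lr * factor ** (epoch // interval)


class SGD:
    """Plain SGD with heavy-ball momentum: v <- mu v + g; p <- p - lr v."""

    def __init__(self, named_params: list[tuple[str, Tensor]], lr: float = 0.01,
                 momentum: float = 0.9):
        self.named_params = list(named_params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.velocity = {name: np.zeros_like(p.data)
                         for name, p in self.named_params}

    def zero_grad(self):
        for _, p in self.named_params:
            p.zero_grad()

    def step(self):
        for name, p in self.named_params:
            if p.grad is None:
                continue
            v = self.velocity[name]
            v *= self.momentum
            v += p.grad.astype(v.dtype)
            p.data = p.data - self.lr * v

    # ------------------------------------------------------------ checkpoint
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"velocity.{k}": v for k, v in self.velocity.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k in self.velocity:
            self.velocity[k] = np.array(state[f"velocity.{k}"],
                                        dtype=self.velocity[k].dtype)
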