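"""Adaptive-moment (Adam) optimizer with the canonical default settings."""

from __future__ import annotations

import numpy as np

from .layers import Sequential

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first/second moment estimates.

    Defaults follow the standard recommendation (beta1=0.9, beta2=0.999,
    eps=1e-8).  Operates in place on the parameters of one or more
    :class:`~jointcal.nn.layers.Sequential` stacks.
    """

    def __init__(self, stacks: list[Sequential], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.stacks = list(stacks)
        self.lr = float(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, int, str], np.ndarray] = {}
        self._v: dict[tuple[int, int, str], np.ndarray] = {}
        for s, stack in enumerate(self.stacks):
            for i, name, p in stack.parameters():
                self._m[(s, i, name)] = np.zeros_like(p)
                self._v[(s, i, name)] = np.zeros_like(p)

    def zero_grad(self) -> None:
        for stack in self.stacks:
            stack.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for s, stack in enumerate(self.stacks):
            for i, layer in enumerate(stack.layers):
                for name, p in layer.params.items():
                    g = layer.grads[name]
                    m = self._m[(s, i, name)]
                    v = self._v[(s, i, name)]
                    m *= self.beta1
                    m += (1 - self.beta1) * g
                    v *= self.beta2
                    v += (1 - self.beta2) * g * g
                    p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
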