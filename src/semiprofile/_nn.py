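"""Tiny neural-network layer/optimizer toolkit on top of the autodiff engine.

Kaiming-initialized linear layers, an Adam optimizer with L2 weight decay,
and parameter state snapshot/restore used for checkpointing and early
stopping.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Parameter", "Linear", "Adam", "collect_state", "load_state"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Linear:
    """Affine map ``x @ W + b`` with Kaiming-normal weight initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x):
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
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
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def collect_state(named_params: dict) -> dict:
    """Copy parameter arrays into a plain dict (checkpoint snapshot)."""
    return {k: p.data.copy() for k, p in named_params.items()}


def load_state(named_params: dict, state: dict) -> None:
    for k, p in named_params.items():
        p.data[...] = state[k]
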