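"""Optimizers operating on flat ``{name: ndarray}`` parameter dicts."""

from __future__ import annotations

import numpy as np


class SGD:
    """Plain gradient descent: p <- p - lr * g."""

    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for name, p in self.params.items():
            p -= np.asarray(self.lr, dtype=p.dtype) * grads[name]


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for name, p in self.params.items():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= np.asarray(
                self.lr, dtype=p.dtype
            ) * (m / c1) / (np.sqrt(v / c2) + self.eps)


def make_optimizer(name: str, params: dict[str, np.ndarray], lr: float):
    if name == "adam":
        return Adam(params, lr)
    if name == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer: {name!r}")
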