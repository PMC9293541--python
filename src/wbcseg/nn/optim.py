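"""Adam optimizer over in-place parameter/gradient array references."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._pairs: list[tuple[np.ndarray, np.ndarray]] = []
        for layer in layers:
            for name in layer.params:
                self._pairs.append((layer.params[name], layer.grads[name]))
        self._m = [np.zeros_like(p) for p, _ in self._pairs]
        self._v = [np.zeros_like(p) for p, _ in self._pairs]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for (p, g), m, v in zip(self._pairs, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
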