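"""Adam optimizer over (layer, parameter-name) pairs."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, parameters, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.parameters = list(parameters)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(layer.params[name]) for layer, name in self.parameters]
        self._v = [np.zeros_like(layer.params[name]) for layer, name in self.parameters]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.parameters):
            g = layer.grads.get(name)
            if g is None:
                continue
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1 ** self.t)
            v_hat = self._v[i] / (1 - b2 ** self.t)
            layer.params[name] -= (self.lr * m_hat /
                                   (np.sqrt(v_hat) + self.eps)).astype(layer.params[name].dtype)
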