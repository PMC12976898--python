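"""Small numerical building blocks for the morphology network.

A compact, dependency-light implementation: exact GELU (erf form) with its
analytic derivative, and an Adam optimizer over a dict of named arrays.
Everything is driven by explicitly seeded numpy generators so training is
bit-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["gelu", "gelu_grad", "Adam"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) * _INV_SQRT_2PI
    Phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return Phi + x * phi


class Adam:
    """Adaptive-moment optimizer over a name -> array parameter dict."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if k not in self._m:
                self._m[k] = np.zeros_like(params[k])
                self._v[k] = np.zeros_like(params[k])
            m = self._m[k]
            v = self._v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            params[k] -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
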