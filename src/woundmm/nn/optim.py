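"""Adam optimizer and the two fused loss functions used by the classifiers."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction (Keras-style defaults, eps=1e-7)."""

    def __init__(
        self,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.lr = float(learning_rate)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.eps = float(eps)
        self._state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self._t = 0

    def step(self, layers) -> None:
        """Apply one update to every trainable layer's accumulated gradients."""
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for layer in layers:
            slot = self._state.setdefault(id(layer), {})
            for name, g in layer.grads.items():
                p = layer.params[name]
                if name not in slot:
                    slot[name] = (np.zeros_like(p), np.zeros_like(p))
                m, v = slot[name]
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * (g * g)
                p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


def sparse_categorical_crossentropy(
    probs: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean NLL of integer labels under softmax output; returns logit gradient."""
    n = probs.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), y] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


def binary_crossentropy(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean BCE for a single sigmoid output; returns logit gradient."""
    p = probs.reshape(-1)
    yf = y.astype(p.dtype)
    eps = 1e-12
    loss = -(yf * np.log(p + eps) + (1 - yf) * np.log(1 - p + eps)).mean()
    grad = ((p - yf) / p.shape[0]).reshape(probs.shape)
    return float(loss), grad
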