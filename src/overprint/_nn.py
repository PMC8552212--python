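"""Minimal fully-connected network with Adam, in float32 NumPy.

Kept deliberately small: dense layers with ReLU hidden activations and a
linear output head are all the encoder needs, and a self-contained forward /
backward pair keeps training single-threaded-deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    """Feed-forward net ``in_dim -> hidden ... -> out_dim`` (ReLU, linear head)."""

    def __init__(self, in_dim: int, hidden: tuple[int, ...], out_dim: int,
                 rng: np.random.Generator):
        sizes = [in_dim, *hidden, out_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(2.0 / a) if i < len(sizes) - 2 else np.sqrt(1.0 / a)
            self.weights.append((rng.standard_normal((a, b)) * scale).astype(np.float32))
            self.biases.append(np.zeros(b, dtype=np.float32))
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Return outputs (and the activation cache when training)."""
        h = np.asarray(x, dtype=np.float32)
        cache = [h]
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                np.maximum(h, 0.0, out=h)
            if keep_cache:
                cache.append(h)
        return (h, cache) if keep_cache else h

    def backward(self, cache: list[np.ndarray], grad_out: np.ndarray):
        """Gradients of sum(loss) w.r.t. parameters given dL/d(output)."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        g = grad_out.astype(np.float32)
        for i in range(len(self.weights) - 1, -1, -1):
            h_in = cache[i]
            grads_w[i] = h_in.T @ g
            grads_b[i] = g.sum(axis=0)
            if i > 0:
                g = g @ self.weights[i].T
                g[cache[i] <= 0.0] = 0.0   # ReLU mask of the producing layer
        return grads_w, grads_b

    def adam_step(self, grads_w, grads_b, lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self._adam_t += 1
        t = self._adam_t
        params = self.weights + self.biases
        grads = list(grads_w) + list(grads_b)
        bc1 = 1.0 - beta1 ** t
        bc2 = 1.0 - beta2 ** t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1.0 - beta1) * g
            v *= beta2
            v += (1.0 - beta2) * np.square(g)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_state(cls, state: dict[str, np.ndarray]) -> "MLP":
        n_layers = sum(1 for k in state if k.startswith("w"))
        obj = cls.__new__(cls)
        obj.weights = [np.asarray(state[f"w{i}"], dtype=np.float32) for i in range(n_layers)]
        obj.biases = [np.asarray(state[f"b{i}"], dtype=np.float32) for i in range(n_layers)]
        obj._adam_m = [np.zeros_like(w) for w in obj.weights + obj.biases]
        obj._adam_v = [np.zeros_like(w) for w in obj.weights + obj.biases]
        obj._adam_t = 0
        return obj
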