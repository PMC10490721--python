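"""Compact feedforward network engine (numpy): dense/ReLU layers, 4-way
softmax head, cross-entropy loss, Adam optimizer.

Sized for the small clinical-scale datasets this package targets
(hundreds of utterances, input dims up to ~800); deliberately minimal
but fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MLP:
    """Dense ReLU network with a softmax output layer."""

    def __init__(self, in_dim: int, hidden: tuple[int, ...], out_dim: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [in_dim, *hidden, out_dim]
        self.weights = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(dims, dims[1:])
        ]
        self.biases = [np.zeros(b) for b in dims[1:]]
        self.hidden = tuple(hidden)
        self.in_dim = in_dim
        self.out_dim = out_dim

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def logits(self, x: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if a.shape[1] != self.in_dim:
            raise ValueError(f"expected input dim {self.in_dim}, got {a.shape[1]}")
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
        return a @ self.weights[-1] + self.biases[-1]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = softmax(self.logits(x))
        return p[0] if np.asarray(x).ndim == 1 else p

    def _forward_backward(self, x: np.ndarray, y: np.ndarray):
        acts = [x]
        a = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
            acts.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        p = softmax(logits)
        n = len(y)
        loss = -np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12)))
        grad = p.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        gw, gb = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            gw.append(acts[i].T @ grad)
            gb.append(grad.sum(axis=0))
            if i > 0:
                grad = (grad @ self.weights[i].T) * (acts[i] > 0)
        return loss, gw[::-1], gb[::-1]

    def snapshot(self):
        return ([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def restore(self, snap) -> None:
        self.weights = [w.copy() for w in snap[0]]
        self.biases = [b.copy() for b in snap[1]]


class Adam:
    def __init__(self, model: MLP, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.mw = [np.zeros_like(w) for w in model.weights]
        self.vw = [np.zeros_like(w) for w in model.weights]
        self.mb = [np.zeros_like(b) for b in model.biases]
        self.vb = [np.zeros_like(b) for b in model.biases]

    def step(self, gw, gb) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for i, (g, m, v) in enumerate(zip(gw, self.mw, self.vw)):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g**2
            self.model.weights[i] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
        for i, (g, m, v) in enumerate(zip(gb, self.mb, self.vb)):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g**2
            self.model.biases[i] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def train_epoch(
    model: MLP, opt: Adam, x: np.ndarray, y: np.ndarray,
    batch_size: int, rng: np.random.Generator,
) -> float:
    order = rng.permutation(len(y))
    total = 0.0
    for start in range(0, len(y), batch_size):
        sel = order[start: start + batch_size]
        loss, gw, gb = model._forward_backward(x[sel], y[sel])
        opt.step(gw, gb)
        total += loss * len(sel)
    return total / len(y)
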