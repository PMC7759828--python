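"""Minimal feed-forward network machinery shared by the propensity and survival models.

The networks used in this package are small fully connected stacks (at most two
hidden layers, widths of a few dozen), so the forward/backward passes are written
directly in NumPy.  Layers are dense affine maps with rectifier (ReLU) hidden
activations; the output layer is linear (a sigmoid, where needed, is applied by
the caller together with its matching loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "SGDNesterov", "Adam", "cyclical_lr"]


@dataclass
class MLP:
    """Fully connected network with ReLU hidden layers and a linear output.

    Parameters are held as lists of weight matrices ``W[l]`` with shape
    (fan_in, fan_out) and bias vectors ``b[l]``.  ``hidden=()`` gives a purely
    linear (single affine) model.
    """

    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)

    @classmethod
    def init(cls, n_inputs: int, hidden: tuple[int, ...], n_outputs: int = 1,
             rng: np.random.Generator | None = None) -> "MLP":
        rng = rng if rng is not None else np.random.default_rng()
        sizes = [n_inputs, *hidden, n_outputs]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, appropriate for rectifier hidden units
            scale = np.sqrt(2.0 / fan_in)
            weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(weights, biases)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Forward pass; if ``cache`` is a list it receives the layer inputs."""
        a = np.asarray(X, dtype=float)
        for l in range(self.n_layers):
            if cache is not None:
                cache.append(a)
            a = a @ self.weights[l] + self.biases[l]
            if l < self.n_layers - 1:
                a = np.maximum(a, 0.0)
        return a

    def backward(self, cache: list, dout: np.ndarray):
        """Backprop ``dout`` (dL/d pre-activation output) through the cached pass.

        Returns (dW list, db list) matching ``self.weights``/``self.biases``.
        """
        dW = [None] * self.n_layers
        db = [None] * self.n_layers
        delta = np.asarray(dout, dtype=float)
        for l in range(self.n_layers - 1, -1, -1):
            a_in = cache[l]
            dW[l] = a_in.T @ delta
            db[l] = delta.sum(axis=0)
            if l > 0:
                delta = delta @ self.weights[l].T
                # ReLU gate: the input to layer l was the rectified output of l-1
                delta = delta * (cache[l] > 0)
        return dW, db

    def params(self):
        return self.weights + self.biases

    def copy(self) -> "MLP":
        return MLP([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def accumulated_weights(self) -> np.ndarray:
        """Product of the layer weight matrices, W_L ... W_1.

        Linearizes the network by dropping biases and activation nonlinearities,
        yielding one overall contribution scalar per input feature (per output).
        """
        acc = self.weights[0]
        for W in self.weights[1:]:
            acc = acc @ W
        return acc[:, 0] if acc.shape[1] == 1 else acc

    def to_dict(self) -> dict:
        return {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        return cls([np.asarray(w, dtype=float) for w in d["weights"]],
                   [np.asarray(b, dtype=float) for b in d["biases"]])


class SGDNesterov:
    """Stochastic gradient descent with Nesterov momentum."""

    def __init__(self, params: list, lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list) -> None:
        mu = self.momentum
        for p, v, g in zip(self.params, self.velocity, grads):
            v_prev = v.copy()
            v *= mu
            v -= self.lr * g
            # Nesterov lookahead update
            p += -mu * v_prev + (1.0 + mu) * v


class Adam:
    """Adaptive moment estimation optimizer."""

    def __init__(self, params: list, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v, g in zip(self.params, self.m, self.v, grads):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def cyclical_lr(epoch: int, base_lr: float, period: int = 20) -> float:
    """Triangular cyclical learning rate oscillating in [base_lr/4, base_lr].

    One full triangle (up then down) spans ``period`` epochs.
    """
    lo, hi = base_lr / 4.0, base_lr
    half = period / 2.0
    pos = epoch % period
    frac = pos / half if pos <= half else (period - pos) / half
    return lo + (hi - lo) * frac
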