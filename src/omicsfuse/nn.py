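"""Minimal seeded feedforward network engine.

The integration models in this package are small fully connected
autoencoders and task heads, so the engine is deliberately compact: dense
layers with explicit backward passes, a couple of activations, and an Adam
optimizer. Everything is float32 and every source of randomness is an
explicit :class:`numpy.random.Generator`, which makes training runs exactly
reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ReLU", "Sigmoid", "MLP", "Adam"]

_DTYPE = np.float32


class Layer:
    """Base class: a differentiable map with optional parameters."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self):
        """Yield (param, grad) array pairs; arrays are updated in place."""
        return ()


class Dense(Layer):
    """Affine layer ``x @ W + b`` with uniform fan-in initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d_in)
        self.W = rng.uniform(-bound, bound, size=(d_in, d_out)).astype(_DTYPE)
        self.b = rng.uniform(-bound, bound, size=(d_out,)).astype(_DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def parameters(self):
        yield self.W, self.gW
        yield self.b, self.gb


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class MLP(Layer):
    """A sequential stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(state) != len(params):
            raise ValueError("state does not match network architecture")
        for (p, _), s in zip(params, state):
            p[...] = s


class Adam:
    """Adam optimizer over the parameters of one or more modules.

    Maintains first/second moment estimates per parameter; ``step`` applies
    one update from the gradients currently stored in the layers.
    """

    def __init__(self, modules, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = [pg for m in modules for pg in m.parameters()]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self._tmp = [np.empty_like(p) for p, _ in self.pairs]

    def step(self) -> None:
        """One update from the gradients currently stored in the layers.

        Uses the folded bias correction ``alpha_t = lr * sqrt(1-b2^t)/(1-b1^t)``
        so each parameter needs a single scratch buffer.
        """
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        alpha = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for (p, g), m, v, tmp in zip(self.pairs, self.m, self.v, self._tmp):
            m *= b1
            np.multiply(g, 1.0 - b1, out=tmp)
            m += tmp
            v *= b2
            np.multiply(g, g, out=tmp)
            tmp *= 1.0 - b2
            v += tmp
            np.sqrt(v, out=tmp)
            tmp += self.eps
            np.divide(m, tmp, out=tmp)
            tmp *= alpha
            p -= tmp
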