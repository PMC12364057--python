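"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed to train the spiking circuit
(surrogate-gradient backpropagation through time), the variational
autoencoders, and the latent dynamics model: elementwise arithmetic with
broadcasting, matrix products, the usual nonlinearities, reductions, and a
Heaviside step whose backward pass is the derivative of a scaled logistic
(the surrogate-gradient trick).

Gradients accumulate in ``Tensor.grad`` after calling ``backward()`` on a
scalar result. All data is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "exp", "log", "spike_surrogate", "Adam", "Linear", "MLP"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += _unbroadcast(-g, a.data.shape)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g * p * a.data ** (p - 1.0)
        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a.grad += g @ b.data.T
            if b.requires_grad:
                b.grad += a.data.T @ g
        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a.grad += np.broadcast_to(g, a.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a.grad += np.broadcast_to(gg, a.data.shape)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a.grad += g.reshape(a.data.shape)
        return self._make(self.data.reshape(*shape), (self,), backward)

    def clamp_min(self, lo: float):
        mask = (self.data > lo).astype(np.float64)
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a.grad += g * m
        return self._make(np.maximum(self.data, lo), (self,), backward)

    # -- backward pass ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# -- elementwise functions ----------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    def backward(g, a=x, s=s):
        if a.requires_grad:
            a.grad += g * s * (1.0 - s)
    return Tensor._make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    def backward(g, a=x, t=t):
        if a.requires_grad:
            a.grad += g * (1.0 - t * t)
    return Tensor._make(t, (x,), backward)


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    def backward(g, a=x, e=e):
        if a.requires_grad:
            a.grad += g * e
    return Tensor._make(e, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g, a=x):
        if a.requires_grad:
            a.grad += g / a.data
    return Tensor._make(np.log(x.data), (x,), backward)


def spike_surrogate(v_minus_theta: Tensor, slope: float = 10.0) -> Tensor:
    """Heaviside step forward; logistic-derivative surrogate backward.

    Forward output is 1 where ``v - theta >= 0`` else 0.  The backward pass
    uses d/dx sigma(slope*x) = slope * s * (1 - s), which equals slope/4 at
    the threshold.
    """
    out = (v_minus_theta.data >= 0.0).astype(np.float64)
    s = 1.0 / (1.0 + np.exp(-slope * np.clip(v_minus_theta.data, -50.0 / slope, 50.0 / slope)))
    def backward(g, a=v_minus_theta, s=s):
        if a.requires_grad:
            a.grad += g * slope * s * (1.0 - s)
    return Tensor._make(out, (v_minus_theta,), backward)


# -- optimizer and layers ---------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Linear:
    """Dense layer, row-vector convention: y = x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Fully connected network with tanh hidden activations."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 out_activation: str = "linear"):
        self.sizes = list(sizes)
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = tanh(layer(x))
        x = self.layers[-1](x)
        if self.out_activation == "sigmoid":
            x = sigmoid(x)
        return x

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = np.tanh(layer.forward_np(x))
        x = self.layers[-1].forward_np(x)
        if self.out_activation == "sigmoid":
            x = 1.0 / (1.0 + np.exp(-x))
        return x

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p.data = np.array(w, dtype=np.float64)
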