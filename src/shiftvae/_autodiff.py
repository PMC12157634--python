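"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the hybrid causal autoencoder needs: dense
affine maps, elementwise nonlinearities, reductions, broadcasting arithmetic
and a custom linear-SCM solve node. Everything is float64. Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Linear", "MLP", "Adam", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and (p.requires_grad or p._parents):
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not (parent.requires_grad or parent._parents):
                    continue
                pid = id(parent)
                if pid in grads:
                    grads[pid] = grads[pid] + pg
                else:
                    grads[pid] = pg

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bwd(g):
            return ((a, _unbroadcast(g, a.data.shape)),
                    (b, _unbroadcast(g, b.data.shape)))

        return Tensor(a.data + b.data, parents=(a, b), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.data, parents=(a,), backward=lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bwd(g):
            return ((a, _unbroadcast(g * b.data, a.data.shape)),
                    (b, _unbroadcast(g * a.data, b.data.shape)))

        return Tensor(a.data * b.data, parents=(a, b), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / float(other))

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def bwd(g):
            return ((a, g * p * a.data ** (p - 1.0)),)

        return Tensor(a.data ** p, parents=(a,), backward=bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def bwd(g):
            return ((a, g @ b.data.T), (b, a.data.T @ g))

        return Tensor(a.data @ b.data, parents=(a, b), backward=bwd)

    # -- elementwise ---------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor(out_data, parents=(a,), backward=lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return Tensor(np.log(a.data), parents=(a,),
                      backward=lambda g: ((a, g / a.data),))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor(out_data, parents=(a,),
                      backward=lambda g: ((a, g * (1.0 - out_data ** 2)),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor(np.where(mask, a.data, 0.0), parents=(a,),
                      backward=lambda g: ((a, g * mask),))

    # -- shape / reductions ----------------------------------------------------
    def reshape(self, *shape):
        a = self
        orig = a.data.shape
        return Tensor(a.data.reshape(*shape), parents=(a,),
                      backward=lambda g: ((a, g.reshape(orig)),))

    @property
    def T(self):
        a = self
        return Tensor(a.data.T, parents=(a,), backward=lambda g: ((a, g.T),))

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.data.shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g2, a.data.shape).copy()),)

        return Tensor(a.data.sum(axis=axis, keepdims=keepdims),
                      parents=(a,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[ax] for ax in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# layers and optimizer
# ---------------------------------------------------------------------------

class Linear:
    """Affine map ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class MLP:
    """Fully connected network with ReLU hidden activations, linear output."""

    def __init__(self, n_in: int, hidden: Sequence[int], n_out: int,
                 rng: np.random.Generator):
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(dims[i], dims[i + 1], rng)
                       for i in range(len(dims) - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam optimiser with bias correction."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
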