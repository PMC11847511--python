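"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough tape-based autodiff to express and train the patch-attention
deconvolution model: broadcast-aware arithmetic, batched matmul,
softmax, layer normalisation and the pointwise nonlinearities, all in
float64.  Gradients accumulate into ``Tensor.grad`` after
``Tensor.backward()`` over a topologically sorted tape.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "stack", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate d(self)/d(leaf) for every reachable leaf."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [(self, False)]
        while stack_:  # iterative DFS: graphs can exceed recursion limits
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- shape helpers -------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._node(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        a = self
        out_data = a.data**exponent

        def backward(g):
            if a.requires_grad:
                a._accum(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._node(out_data, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._node(a.data @ b.data, (a, b), backward)

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._node(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._node(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._node(s, (a,), backward)

    def gelu(self):
        """Exact Gaussian-error-linear unit 0.5 x (1 + erf(x/sqrt(2)))."""
        a = self
        x = a.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (phi + x * pdf))

        return Tensor._node(x * phi, (a,), backward)

    def softmax(self):
        """Softmax over the last axis."""
        a = self
        z = a.data - a.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            if a.requires_grad:
                dot = (g * y).sum(axis=-1, keepdims=True)
                a._accum(y * (g - dot))

        return Tensor._node(y, (a,), backward)

    def layernorm(self, eps: float = 1e-5):
        """Normalise the last axis to zero mean, unit variance (no affine)."""
        a = self
        mu = a.data.mean(axis=-1, keepdims=True)
        xc = a.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv

        def backward(g):
            if a.requires_grad:
                gy = g * inv
                a._accum(
                    gy
                    - gy.mean(axis=-1, keepdims=True)
                    - y * (gy * y).mean(axis=-1, keepdims=True)
                )

        return Tensor._node(y, (a,), backward)

    # -- shape ops -----------------------------------------------------

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._node(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = tuple(ax % a.data.ndim for ax in axes)
        inverse = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(*inverse))

        return Tensor._node(a.data.transpose(*axes), (a,), backward)

    def __getitem__(self, key):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accum(full)

        return Tensor._node(a.data[key], (a,), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis."""
    parents = tuple(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(parents):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._node(data, parents, backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along an existing axis."""
    parents = tuple(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(parents, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._node(data, parents, backward)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
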