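"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to express and train the transformer aggregator:
broadcast-aware add/mul, (stacked) matmul, ReLU, last-axis softmax and
standardization (the layer-norm core), reshape/transpose, reductions and
scalar powers.  Gradients are accumulated by topological-order backward
passes.  Everything is float64 and single-threaded, which keeps training
runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------
    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=float))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ---- operations ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        out._backward = bwd
        return out

    def softmax(self):
        """Numerically stable softmax along the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=-1, keepdims=True)))

        out._backward = bwd
        return out

    def standardize(self, eps: float = 1e-5):
        """(x - mean) / sqrt(var + eps) along the last axis (layer-norm core)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = Tensor(y, parents=(self,))
        n = self.data.shape[-1]

        def bwd(g):
            if self.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gy = (g * y).mean(axis=-1, keepdims=True)
                self._accum(inv * (g - gm - y * gy))

        out._backward = bwd
        _ = n
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_rows(tensors) -> Tensor:
    """Concatenate 2-D tensors along axis 0 (rows)."""
    parents = tuple(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0), parents=parents)
    sizes = [t.data.shape[0] for t in tensors]

    def bwd(g):
        start = 0
        for t, n in zip(parents, sizes):
            if t.requires_grad:
                t._accum(g[start:start + n])
            start += n

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def gradient_check(fn, x: np.ndarray, eps: float = 1e-6) -> float:
    """Max abs difference between analytic and finite-difference gradients.

    ``fn`` maps a Tensor to a scalar Tensor.
    """
    t = Tensor(x.copy(), requires_grad=True)
    out = fn(t)
    out.backward()
    analytic = t.grad.copy()
    numeric = np.zeros_like(x, dtype=float)
    flat = x.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(Tensor(x)).data.item()
        flat[i] = orig - eps
        lo = fn(Tensor(x)).data.item()
        flat[i] = orig
        numeric.reshape(-1)[i] = (hi - lo) / (2 * eps)
    return float(np.abs(analytic - numeric).max())
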