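"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just the operations the graph auto-encoder needs: matmul, broadcast add/mul,
relu, sigmoid, exp, sum, reshape/transpose, and numerically stable
cross-entropy-from-logits primitives. Gradients are accumulated on leaf
tensors by :meth:`Tensor.backward` via a topological sort of the tape.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward):
        return Tensor(data, parents=parents, backward=backward)

    # ---- ops -------------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            if a.ndim == 1 and b.ndim == 2:      # vector @ matrix
                return (g @ b.T, np.outer(a, g))
            if a.ndim == 2 and b.ndim == 1:      # matrix @ vector
                return (np.outer(g, b), a.T @ g)
            if a.ndim == 1 and b.ndim == 1:      # inner product
                return (g * b, g * a)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 0.5 * (np.tanh(0.5 * self.data) + 1.0)  # stable logistic
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return self._make(e, (self,), lambda g: (g * e,))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    def transpose2d(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    def bce_with_logits(self, target: np.ndarray, weight=None):
        """Elementwise binary cross-entropy from logits, summed.

        Stable form: max(x,0) - x*t + log(1+exp(-|x|)); gradient sigmoid(x)-t.
        """
        x, t = self.data, np.asarray(target, dtype=np.float64)
        w = np.ones_like(x) if weight is None else np.asarray(weight, dtype=np.float64)
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        s = 0.5 * (np.tanh(0.5 * x) + 1.0)

        def backward(g):
            return (g * w * (s - t),)

        return self._make((w * loss).sum(), (self,), backward)

    def softmax_cross_entropy(self, target: np.ndarray, row_mask=None):
        """Row-wise categorical cross-entropy from logits, summed over rows.

        `target` holds one-hot rows; `row_mask` (0/1 per row) excludes padding.
        """
        x = self.data
        t = np.asarray(target, dtype=np.float64)
        m = np.ones(x.shape[0]) if row_mask is None else np.asarray(row_mask, float)
        xs = x - x.max(axis=1, keepdims=True)
        lse = np.log(np.exp(xs).sum(axis=1))
        p = np.exp(xs) / np.exp(xs).sum(axis=1, keepdims=True)
        row_loss = lse - (xs * t).sum(axis=1)

        def backward(g):
            return (g * m[:, None] * (p - t),)

        return self._make((m * row_loss).sum(), (self,), backward)

    # ---- backward pass ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def parameter(array: np.ndarray) -> Tensor:
    return Tensor(array, requires_grad=True)


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter Tensors."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
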