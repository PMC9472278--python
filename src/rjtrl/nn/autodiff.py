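"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine sized for this package's needs: tree-structured
GRU message passing, two-layer MLP heads and PPO losses.  Tensors wrap
float64 ndarrays; gradients are accumulated by a topological backward sweep.
Broadcasting is supported for ``+`` and ``*`` via gradient unbroadcasting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "constant",
    "concat",
    "stack",
    "minimum",
    "log_softmax",
    "Adam",
]


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
    return grad


class Tensor:
    __slots__ = ("data", "parents", "_backward", "grad", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self._backward = backward
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph ------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += -g

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2, other.data.shape)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if a.ndim == 2 and b.ndim == 1:
                    self.grad += np.outer(g, b)
                elif a.ndim == 1 and b.ndim == 2:
                    self.grad += b @ g
                else:
                    self.grad += g @ np.swapaxes(b, -1, -2)
            if other.requires_grad:
                if a.ndim == 2 and b.ndim == 1:
                    other.grad += a.T @ g
                elif a.ndim == 1 and b.ndim == 2:
                    other.grad += np.outer(a, g)
                else:
                    other.grad += np.swapaxes(a, -1, -2) @ g

        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        out._backward = bw
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * (1.0 - t * t)

        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * e

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g / self.data

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp with zero gradient outside [lo, hi] (PPO ratio clipping)."""
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            if self.requires_grad:
                self.grad += g * inside

        out._backward = bw
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.data)

        out._backward = bw
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), (self,))

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.data) / n

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        out._backward = bw
        return out

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor({self.data!r})"


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def concat(tensors) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[0] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors]), tuple(tensors))
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t.grad += g[a:b]

    out._backward = bw
    return out


def stack(tensors) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors]), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t.grad += g[i]

    out._backward = bw
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum; gradient flows to the smaller operand (ties go
    to the first)."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data <= b.data
    out = Tensor(np.where(take_a, a.data, b.data), (a, b))

    def bw(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * take_a, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * ~take_a, b.data.shape)

    out._backward = bw
    return out


#: logit value used for masked categories; finite so that exp() underflows to
#: exactly zero without producing NaNs in entropy terms
MASK_LOGIT = -1e9


def log_softmax(logits: Tensor, mask=None) -> Tensor:
    """Numerically stable log-softmax over a 1-D logit vector.

    ``mask`` (boolean, True = allowed) sends disallowed categories to an
    effectively -inf logit; their probability is exactly zero.
    """
    x = logits
    if mask is not None:
        m = np.where(mask, 0.0, MASK_LOGIT)
        x = x + Tensor(m)
    z = x.data
    c = z.max()
    lse = c + np.log(np.exp(z - c).sum())
    out = Tensor(z - lse, (x,))
    p = np.exp(out.data)

    def bw(g):
        if x.requires_grad:
            x.grad += g - p * g.sum()

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params, lr=3e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
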