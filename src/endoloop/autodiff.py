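"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the forecaster and controller need:
broadcast-aware arithmetic, matmul, the usual pointwise nonlinearities,
reductions, concatenation/stacking and basic slicing. Everything is float64.

A :class:`Tensor` records its parents and a backward closure; calling
``backward()`` on a scalar-valued tensor accumulates ``grad`` on every
tensor created with ``requires_grad=True``. The graph is rebuilt on every
forward pass (define-by-run), so there is no retained state between calls.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "sigmoid", "relu",
           "leaky_relu", "tanh", "exp", "log", "sqrt", "absolute", "maximum0"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative topological sort (graphs from long rollouts are deep)
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.value.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value + other.value, _parents=(self, other))
        def bw(g):
            self._accum(g); other._accum(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value - other.value, _parents=(self, other))
        def bw(g):
            self._accum(g); other._accum(-g)
        out._backward = bw
        return out

    def __rsub__(self, other):
        return as_tensor(other).__sub__(self)

    def __neg__(self):
        out = Tensor(-self.value, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value * other.value, _parents=(self, other))
        def bw(g):
            self._accum(g * other.value); other._accum(g * self.value)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value / other.value, _parents=(self, other))
        def bw(g):
            self._accum(g / other.value)
            other._accum(-g * self.value / (other.value ** 2))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other).__truediv__(self)

    def __pow__(self, exponent: float):
        out = Tensor(self.value ** exponent, _parents=(self,))
        out._backward = lambda g: self._accum(g * exponent * self.value ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.value @ other.value, _parents=(self, other))
        def bw(g):
            a, b = self.value, other.value
            if a.ndim == 1 and b.ndim == 1:        # inner product -> scalar
                self._accum(g * b)
                other._accum(g * a)
            elif b.ndim == 1:                       # (..., m, k) @ (k,) -> (..., m)
                self._accum(np.expand_dims(g, -1) * b)
                gb = (a * np.expand_dims(g, -1)).reshape(-1, a.shape[-1]).sum(axis=0)
                other._accum(gb)
            elif a.ndim == 1:                       # (k,) @ (..., k, n) -> (..., n)
                ga = (b @ np.expand_dims(g, -1))[..., 0]
                self._accum(ga.reshape(-1, a.shape[0]).sum(axis=0)
                            if ga.ndim > 1 else ga)
                other._accum(a[:, None] * np.expand_dims(g, -2))
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accum(_unbroadcast(ga, a.shape))
                other._accum(_unbroadcast(gb, b.shape))
        out._backward = bw
        return out

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.value.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.value.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.value.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.value.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.value.transpose(axes), _parents=(self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accum(g.transpose(inv) if inv is not None else g.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], _parents=(self,))
        def bw(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = bw
        return out

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value.copy())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise nonlinearities ------------------------------------------------

def _unary(x: Tensor, value: np.ndarray, local_grad: np.ndarray) -> Tensor:
    out = Tensor(value, _parents=(x,))
    out._backward = lambda g: x._accum(g * local_grad)
    return out


def tanh(x) -> Tensor:
    x = as_tensor(x)
    v = np.tanh(x.value)
    return _unary(x, v, 1.0 - v ** 2)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    # clip keeps exp finite; sigmoid is saturated beyond +-60 anyway
    v = 1.0 / (1.0 + np.exp(-np.clip(x.value, -60.0, 60.0)))
    return _unary(x, v, v * (1.0 - v))


def relu(x) -> Tensor:
    x = as_tensor(x)
    return _unary(x, np.maximum(x.value, 0.0), (x.value > 0).astype(np.float64))


def leaky_relu(x, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    v = np.where(x.value > 0, x.value, slope * x.value)
    return _unary(x, v, np.where(x.value > 0, 1.0, slope))


def exp(x) -> Tensor:
    x = as_tensor(x)
    v = np.exp(x.value)
    return _unary(x, v, v)


def log(x) -> Tensor:
    x = as_tensor(x)
    return _unary(x, np.log(x.value), 1.0 / x.value)


def sqrt(x) -> Tensor:
    x = as_tensor(x)
    v = np.sqrt(x.value)
    return _unary(x, v, 0.5 / v)


def absolute(x) -> Tensor:
    """|x| with subgradient 0 at x = 0 (keeps kink updates finite)."""
    x = as_tensor(x)
    return _unary(x, np.abs(x.value), np.sign(x.value))


def maximum0(x) -> Tensor:
    """max(0, x) hinge; subgradient 0 at the kink."""
    return relu(x)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.value for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = bw
    return out
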