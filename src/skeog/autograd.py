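"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the relation-extraction model needs:
broadcasting arithmetic, matrix products, pointwise nonlinearities,
reductions, indexing/concatenation, and a pair-scatter primitive used to
assemble edge tensors. Gradients are accumulated by topological-order
backpropagation from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adagrad", "parameter", "sigmoid", "softmax", "cat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g, a=self, p=exponent):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                if b.data.ndim == 1:
                    ga = np.multiply.outer(g, b.data) if a.data.ndim > 1 else g * b.data
                else:
                    ga = g @ b.data.swapaxes(-1, -2)
                a._accum(_unbroadcast(np.asarray(ga), a.data.shape))
            if b.requires_grad:
                if a.data.ndim == 1:
                    gb = np.multiply.outer(a.data, g) if b.data.ndim > 1 else a.data * g
                else:
                    gb = a.data.swapaxes(-1, -2) @ g
                b._accum(_unbroadcast(np.asarray(gb), b.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - od * od))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od * (1.0 - od))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * (a.data > 0.0))

        return Tensor._from_op(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        out_data = np.where(self.data > 0.0, self.data, slope * self.data)

        def backward(g, a=self, s=slope):
            if a.requires_grad:
                a._accum(g * np.where(a.data > 0.0, 1.0, s))

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions / shape ---------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        axes = axes or None
        out_data = self.data.transpose(axes)

        def backward(g, a=self, ax=axes):
            if a.requires_grad:
                inv = np.argsort(ax) if ax is not None else None
                a._accum(g.transpose(inv))

        return Tensor._from_op(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g, a=self, k=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, k, g)
                a._accum(full)

        return Tensor._from_op(out_data, (self,), backward)

    # -- graph plumbing -------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None


# -- free functions -----------------------------------------------------------


def parameter(rng: np.random.Generator, shape, scale: float = 0.05) -> Tensor:
    """A learnable tensor initialised from U(-scale, scale)."""
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # constant shift, no grad path
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along `axis`."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, parts=tensors, offs=offsets, ax=axis):
        for i, t in enumerate(parts):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(offs[i], offs[i + 1])
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g, parts=tensors, ax=axis):
        for i, t in enumerate(parts):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=ax))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def scatter_pairs(values: Tensor, rows: np.ndarray, cols: np.ndarray, n: int) -> Tensor:
    """Build a symmetric (n, n, d) tensor from per-pair vectors.

    Entry (rows[e], cols[e]) and its mirror each receive values[e]; node
    pairs with no edge stay zero.
    """
    d = values.data.shape[1]
    out_data = np.zeros((n, n, d))
    np.add.at(out_data, (rows, cols), values.data)
    np.add.at(out_data, (cols, rows), values.data)

    def backward(g, v=values, r=rows, c=cols):
        if v.requires_grad:
            v._accum(g[r, c] + g[c, r])

    return Tensor._from_op(out_data, (values,), backward)


class Adagrad:
    """Adagrad with global-norm gradient clipping and optional L2 decay."""

    def __init__(self, params: list[Tensor], lr: float = 0.1,
                 eps: float = 1e-8, clip: float = 5.0,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.eps = eps
        self.clip = clip
        self.weight_decay = weight_decay
        self._accum = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad for p in self.params]
        total = np.sqrt(sum(float((g * g).sum()) for g in grads if g is not None))
        scale = self.clip / total if (self.clip and total > self.clip) else 1.0
        for p, acc in zip(self.params, self._accum):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            acc += g * g
            p.data -= self.lr * g / (np.sqrt(acc) + self.eps)
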