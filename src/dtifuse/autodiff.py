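"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training stack needs a small, predictable set of differentiable
operations: dense matmul, sparse-constant matmul (for segment sums over
graph edges), elementwise arithmetic with broadcasting, reductions, row
gathering, and the usual neural activations.  This module provides exactly
those, with gradients accumulated into ``Tensor.grad`` by ``backward()``.

Everything is float64.  Sparse matrices appearing in ``spmm`` are treated
as constants (graph structure), never as parameters.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "concat",
    "bmm",
    "swapaxes",
    "take_rows",
    "spmm",
    "weighted_spmm",
    "relu",
    "leaky_relu",
    "elu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "clip",
    "straight_through_ge",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every requires_grad leaf."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, False)]
            while stack:
                cur, processed = stack.pop()
                if processed:
                    topo.append(cur)
                    continue
                if id(cur) in seen or not cur.requires_grad:
                    continue
                seen.add(id(cur))
                stack.append((cur, True))
                for p in cur._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                parent_grads = node._backward(g)
                for p, pg in zip(node._parents, parent_grads):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad = node.grad + g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        return Tensor(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        base = self.data
        return Tensor(
            base ** p,
            (self,),
            lambda g: (g * p * base ** (p - 1.0),),
        )

    def __matmul__(self, other):
        other = tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a @ b,
            (self, other),
            lambda g: (g @ b.T, a.T @ g),
        )

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor(
            self.data.reshape(*shape),
            (self,),
            lambda g: (g.reshape(orig),),
        )

    @property
    def T(self):
        return Tensor(self.data.T, (self,), lambda g: (g.T,))


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """A trainable leaf.  If ``rng`` is given, ``data`` is a shape tuple."""
    if rng is not None:
        shape = tuple(data)
        if scale is None:
            scale = 1.0 / np.sqrt(shape[0] if shape else 1)
        data = rng.normal(0.0, scale, size=shape)
    return Tensor(data, requires_grad=True)


# -- structural ops ----------------------------------------------------

def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul: a is (n, p, d); b is (d, q) shared or (n, d, q)."""
    a, b = tensor(a), tensor(b)
    ad_, bd = a.data, b.data

    def backward(g):
        if bd.ndim == 2:
            return (g @ bd.T, np.einsum("npd,npq->dq", ad_, g))
        return (g @ bd.swapaxes(-1, -2), ad_.swapaxes(-1, -2) @ g)

    return Tensor(np.matmul(ad_, bd), (a, b), backward)


def swapaxes(x: Tensor, ax1: int, ax2: int) -> Tensor:
    x = tensor(x)
    return Tensor(x.data.swapaxes(ax1, ax2), (x,), lambda g: (g.swapaxes(ax1, ax2),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather; backward scatter-adds into the source rows."""
    x = tensor(x)
    idx = np.asarray(idx)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        return (gx,)

    return Tensor(x.data[idx], (x,), backward)


def spmm(S: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse-constant @ dense, e.g. segment sums over graph edges."""
    x = tensor(x)
    S = S.tocsr()
    St = S.T.tocsr()
    return Tensor(S @ x.data, (x,), lambda g: (St @ g,))


def weighted_spmm(values: Tensor, src: np.ndarray, dst: np.ndarray,
                  n: int, X: Tensor) -> Tensor:
    """out[i] = sum over edges (src=j, dst=i) of values_e * X[j].

    Differentiable in both the per-edge weights (an (E, 1) tensor, e.g.
    attention coefficients) and the dense features X; the sparse structure
    (src, dst) is constant.
    """
    values = tensor(values)
    X = tensor(X)
    A = sp.csr_matrix((values.data[:, 0], (dst, src)), shape=(n, n))
    At = A.T.tocsr()

    def backward(g):
        gv = np.einsum("ed,ed->e", X.data[src], g[dst])[:, None]
        return (gv, At @ g)

    return Tensor(A @ X.data, (values, X), backward)


# -- activations -------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = tensor(x)
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def leaky_relu(x: Tensor, negative_slope: float = 0.2) -> Tensor:
    x = tensor(x)
    mask = x.data > 0
    slope = np.where(mask, 1.0, negative_slope)
    return Tensor(x.data * slope, (x,), lambda g: (g * slope,))


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = tensor(x)
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out = np.where(x.data > 0, x.data, neg)
    deriv = np.where(x.data > 0, 1.0, neg + alpha)
    return Tensor(out, (x,), lambda g: (g * deriv,))


def sigmoid(x: Tensor) -> Tensor:
    x = tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, (x,), lambda g: (g * s * (1.0 - s),))


def exp(x: Tensor) -> Tensor:
    x = tensor(x)
    e = np.exp(x.data)
    return Tensor(e, (x,), lambda g: (g * e,))


def log(x: Tensor) -> Tensor:
    x = tensor(x)
    return Tensor(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    x = tensor(x)
    r = np.sqrt(x.data)
    return Tensor(r, (x,), lambda g: (g * 0.5 / np.maximum(r, 1e-300),))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient passes only through the un-clipped interior."""
    x = tensor(x)
    mask = (x.data > lo) & (x.data < hi)
    return Tensor(np.clip(x.data, lo, hi), (x,), lambda g: (g * mask,))


def straight_through_ge(x: Tensor, threshold: Tensor, tau: float) -> Tensor:
    """Hard indicator ``x >= threshold`` with a sigmoid surrogate gradient.

    Forward emits the exact binary gate; backward flows through
    ``sigmoid((x - threshold) / tau)`` so a learnable threshold receives
    gradients despite the hard forward pass.
    """
    if tau <= 0:
        raise ValueError("tau must be positive in relaxed thresholding")
    x = tensor(x)
    threshold = tensor(threshold)
    hard = (x.data >= threshold.data).astype(np.float64)
    s = 1.0 / (1.0 + np.exp(-(x.data - threshold.data) / tau))
    ds = s * (1.0 - s) / tau

    def backward(g):
        return (
            _unbroadcast(g * ds, x.data.shape),
            _unbroadcast(-g * ds, threshold.data.shape),
        )

    return Tensor(hard, (x, threshold), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data
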