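"""Tape-based reverse-mode automatic differentiation over numpy arrays.

The model's forward pass is written once against the dispatching helpers in
this module (:func:`tanh`, :func:`gather`, ...).  When the inputs are
:class:`Tensor` objects a computation graph is recorded and
:meth:`Tensor.backward` accumulates gradients; when the inputs are plain
``numpy`` arrays the same code runs tape-free, which is what inference and
evaluation use.

Only the operations the model needs are implemented: elementwise arithmetic
with broadcasting, matrix products, the activations, reductions, row
gather/scatter and segment sums.  Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

__all__ = [
    "Tensor",
    "Adam",
    "data",
    "is_tensor",
    "tanh",
    "sigmoid",
    "relu",
    "exp",
    "log",
    "absolute",
    "gather",
    "take_pairs",
    "scatter_pairs",
    "segment_sum",
    "concat",
    "logsumexp",
]


def index_add(acc: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """``acc[idx] += vals`` with repeated indices (sort + reduceat).

    Equivalent to ``np.add.at`` but much faster for long index arrays.
    """
    if idx.size == 0:
        return
    diffs = np.diff(idx)
    if np.all(diffs >= 0):  # already sorted: skip the argsort
        sidx, svals = idx, vals
    else:
        order = np.argsort(idx, kind="stable")
        sidx = idx[order]
        svals = vals[order]
        diffs = np.diff(sidx)
    starts = np.concatenate(([0], np.flatnonzero(diffs) + 1))
    acc[sidx[starts]] += np.add.reduceat(svals, starts, axis=0)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the reverse-mode tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operator
    # instead of producing an object array
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        """Return the underlying array as a tape-free constant."""
        return self.data

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every reachable parent."""
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological order (graphs can be thousands of nodes deep)
        order, seen, stack = [], set(), [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        owned = set()  # parents whose .grad buffer we may mutate in place
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if parent.grad is None:
                    parent.grad = pgrad  # may alias; never mutated unless owned
                elif id(parent) in owned:
                    parent.grad += pgrad
                else:
                    parent.grad = parent.grad + pgrad
                    owned.add(id(parent))

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: a + b,
            lambda g, a, b: g,
            lambda g, a, b: g,
        )

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: a * b,
            lambda g, a, b: g * b,
            lambda g, a, b: g * a,
        )

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: a - b,
            lambda g, a, b: g,
            lambda g, a, b: -g,
        )

    def __rsub__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: b - a,
            lambda g, a, b: -g,
            lambda g, a, b: g,
        )

    def __neg__(self):
        return _unary(self, lambda a: -a, lambda g, a, out: -g)

    def __truediv__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __rtruediv__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: b / a,
            lambda g, a, b: -g * b / (a * a),
            lambda g, a, b: g / a,
        )

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return _unary(self, lambda a: a**p, lambda g, a, out: g * p * a ** (p - 1))

    def __matmul__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: a @ b,
            lambda g, a, b: g @ b.T,
            lambda g, a, b: a.T @ g,
            broadcast=False,
        )

    def __rmatmul__(self, other):
        return _binary(
            self,
            other,
            lambda a, b: b @ a,
            lambda g, a, b: b.T @ g,
            lambda g, a, b: g @ a.T,
            broadcast=False,
        )

    # -- shape / reductions ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a, out):
            if axis is None:
                return np.broadcast_to(g, a.shape)
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, a.shape)

        return _unary(self, lambda a: a.sum(axis=axis, keepdims=keepdims), backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        old = self.data.shape
        return _unary(
            self, lambda a: a.reshape(shape), lambda g, a, out: g.reshape(old)
        )

    @property
    def T(self):
        return _unary(self, lambda a: a.T, lambda g, a, out: g.T)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def data(x) -> np.ndarray:
    """The plain ndarray behind ``x`` whether or not it is taped."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unary(x, f, df):
    if not isinstance(x, Tensor):
        return f(np.asarray(x, dtype=np.float64))
    out_data = f(x.data)

    def backward(g, a=x.data, out=out_data):
        return [(x, _unbroadcast(np.asarray(df(g, a, out)), a.shape))]

    return Tensor(out_data, parents=(x,), backward=backward)


def _binary(x, y, f, dfx, dfy, broadcast=True):
    tx, ty = isinstance(x, Tensor), isinstance(y, Tensor)
    if not tx and not ty:
        return f(data(x), data(y))
    a, b = data(x), data(y)
    out_data = f(a, b)
    parents = tuple(p for p, t in ((x, tx), (y, ty)) if t)

    def backward(g):
        grads = []
        if tx:
            gx = np.asarray(dfx(g, a, b))
            grads.append((x, _unbroadcast(gx, a.shape) if broadcast else gx))
        if ty:
            gy = np.asarray(dfy(g, a, b))
            grads.append((y, _unbroadcast(gy, b.shape) if broadcast else gy))
        return grads

    return Tensor(out_data, parents=parents, backward=backward)


# -- activations ---------------------------------------------------------


def tanh(x):
    return _unary(x, np.tanh, lambda g, a, out: g * (1.0 - out * out))


def sigmoid(x):
    return _unary(
        x,
        lambda a: _expit(a),
        lambda g, a, out: g * out * (1.0 - out),
    )


def relu(x):
    return _unary(x, lambda a: np.maximum(a, 0.0), lambda g, a, out: g * (a > 0))


def exp(x):
    return _unary(x, np.exp, lambda g, a, out: g * out)


def log(x):
    return _unary(x, np.log, lambda g, a, out: g / a)


def absolute(x):
    return _unary(x, np.abs, lambda g, a, out: g * np.sign(a))


# -- indexing / segments --------------------------------------------------


def gather(x, idx):
    """Rows ``x[idx]`` along axis 0; backward scatter-adds."""
    idx = np.asarray(idx)

    def backward(g, a, out):
        acc = np.zeros_like(a)
        index_add(acc, idx, g)
        return acc

    return _unary(x, lambda a: a[idx], backward)


def take_pairs(x, rows, cols):
    """``x[rows, cols]`` as a 1-D result with scatter-add backward."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)

    def backward(g, a, out):
        acc = np.zeros_like(a)
        index_add(acc.reshape(-1), rows * a.shape[1] + cols, g)
        return acc

    return _unary(x, lambda a: a[rows, cols], backward)


def scatter_pairs(values, rows, cols, shape):
    """A zeros(shape) matrix with ``values`` added at ``(rows, cols)``."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)

    def f(v):
        out = np.zeros(shape, dtype=np.float64)
        index_add(out.reshape(-1), rows * shape[1] + cols, v)
        return out

    return _unary(values, f, lambda g, a, out: g[rows, cols])


def segment_sum(x, segments, num_segments):
    """Sum rows of ``x`` grouped by ``segments`` (shape ``(n, ...)``)."""
    segments = np.asarray(segments)

    def f(a):
        out = np.zeros((num_segments,) + a.shape[1:], dtype=np.float64)
        index_add(out, segments, a)
        return out

    return _unary(x, f, lambda g, a, out: g[segments])


def slice_cols(x, lo, hi):
    """Columns ``x[:, lo:hi]``; backward pads with zeros."""

    def backward(g, a, out):
        acc = np.zeros_like(a)
        acc[:, lo:hi] = g
        return acc

    return _unary(x, lambda a: a[:, lo:hi], backward)


def concat(xs, axis=0):
    """Concatenate a mix of Tensors/arrays along ``axis``."""
    if not any(isinstance(x, Tensor) for x in xs):
        return np.concatenate([data(x) for x in xs], axis=axis)
    arrays = [data(x) for x in xs]
    out_data = np.concatenate(arrays, axis=axis)
    sizes = [a.shape[axis] for a in arrays]
    offsets = np.cumsum([0] + sizes)
    parents = tuple(x for x in xs if isinstance(x, Tensor))

    def backward(g):
        grads = []
        for x, start, stop in zip(xs, offsets[:-1], offsets[1:]):
            if isinstance(x, Tensor):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, stop)
                grads.append((x, g[tuple(sl)]))
        return grads

    return Tensor(out_data, parents=parents, backward=backward)


def logsumexp(x, axis=None):
    """Numerically stable log-sum-exp along ``axis`` (keeps gradient)."""
    m = np.max(data(x), axis=axis, keepdims=True)
    shifted = x - m  # max treated as a constant: gradient is exact anyway
    if axis is None:
        return log(exp(shifted).sum()) + float(m.reshape(()))
    return log(exp(shifted).sum(axis=axis)) + np.squeeze(m, axis=axis)


# -- optimizer ------------------------------------------------------------


class Adagrad:
    """Adagrad over a ``{name: Tensor}`` parameter dict."""

    def __init__(self, params: dict, lr=1e-1, eps=1e-10, weight_decay=0.0,
                 clip_norm=None):
        self.params = params
        self.lr = lr
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.g2 = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(
                    float((p.grad**2).sum())
                    for p in self.params.values()
                    if p.grad is not None
                )
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.g2[k] += g * g
            p.data -= self.lr * (
                g / (np.sqrt(self.g2[k]) + self.eps) + self.weight_decay * p.data
            )


class Adam:
    """Adam over a ``{name: Tensor}`` parameter dict.

    ``weight_decay`` is decoupled (applied directly to the weights, scaled
    by the learning rate); ``clip_norm`` rescales the global gradient norm
    before the update when it exceeds the threshold.
    """

    def __init__(
        self,
        params: dict,
        lr=1e-3,
        betas=(0.9, 0.999),
        eps=1e-8,
        weight_decay=0.0,
        clip_norm=None,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(
                    float((p.grad**2).sum())
                    for p in self.params.values()
                    if p.grad is not None
                )
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )
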