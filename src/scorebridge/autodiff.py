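"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports higher-order derivatives: every vector-Jacobian product is itself
expressed in traced operations, so the output of :func:`grad` can be
differentiated again.  This is what the score-matching loss needs — the
Jacobian-trace term requires a derivative with respect to the spatial input
*inside* the loss, followed by a derivative of the whole loss with respect
to the network parameters (hence the twice-differentiability requirement on
activations).

Only the operations needed by the drift networks and losses are provided;
this is not a general tensor library.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor", "as_tensor", "grad",
    "add", "mul", "div", "matmul", "tsum", "tmean",
    "tanh", "exp", "log", "erf", "gelu", "relu",
    "reshape", "broadcast_to", "concat", "transpose",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad=False, _parents=(), _vjps=()):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjps = _vjps

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other, dtype=np.float64))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjps):
    """Create a graph node; constant subgraphs are pruned for speed."""
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, _parents=parents, _vjps=vjps)
    return Tensor(data)


# -- elementwise arithmetic ------------------------------------------------

def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(g, b.shape)),
    )


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        (lambda g: _unbroadcast(mul(g, b), a.shape), lambda g: _unbroadcast(mul(g, a), b.shape)),
    )


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data / b.data,
        (a, b),
        (
            lambda g: _unbroadcast(div(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, div(mul(a, -1.0), mul(b, b))), b.shape),
        ),
    )


def power(a, p):
    """``a ** p`` for a constant scalar exponent ``p``."""
    a = as_tensor(a)
    p = float(p)
    out = _make(a.data ** p, (a,), (lambda g: mul(g, mul(power(a, p - 1.0), p)),))
    return out


# -- linear algebra --------------------------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _make(
        a.data @ b.data,
        (a, b),
        (lambda g: matmul(g, transpose(b)), lambda g: matmul(transpose(a), g)),
    )


def transpose(a, axes=None):
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(np.transpose(a.data, axes), (a,), (lambda g: transpose(g, inv),))


# -- reductions and shape --------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        ax = axis if isinstance(axis, tuple) else (axis,)
        ax = tuple(i % a.ndim for i in ax)
        if not keepdims:
            kshape = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            g = reshape(g, kshape)
        return broadcast_to(g, a.shape)

    return _make(data, (a,), (vjp,))


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = as_tensor(a)
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, a.shape),))


def broadcast_to(a, shape):
    a = as_tensor(a)
    return _make(np.broadcast_to(a.data, shape).copy(), (a,), (lambda g: _unbroadcast(g, a.shape),))


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])

    def make_vjp(k):
        def vjp(g):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
            return getitem(g, tuple(idx))
        return vjp

    return _make(data, tuple(tensors), tuple(make_vjp(k) for k in range(len(tensors))))


def getitem(a, idx):
    a = as_tensor(a)
    return _make(a.data[idx], (a,), (lambda g: _scatter(g, a.shape, idx),))


def _scatter(g, shape, idx):
    g = as_tensor(g)
    out = np.zeros(shape, dtype=np.float64)
    out[idx] += g.data
    return _make(out, (g,), (lambda gg: getitem(gg, idx),))


# -- nonlinearities --------------------------------------------------------

def tanh(a):
    a = as_tensor(a)
    y = np.tanh(a.data)
    out = _make(y, (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, add(1.0, mul(mul(out, out), -1.0))),)
    return out


def exp(a):
    a = as_tensor(a)
    out = _make(np.exp(a.data), (a,), ())
    if out.requires_grad:
        out._vjps = (lambda g: mul(g, out),)
    return out


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: div(g, a),))


def erf(a):
    a = as_tensor(a)
    c = 2.0 / math.sqrt(math.pi)
    return _make(
        _special.erf(a.data),
        (a,),
        (lambda g: mul(g, mul(exp(mul(mul(a, a), -1.0)), c)),),
    )


def gelu(a):
    """Exact (erf-based) GELU; twice differentiable."""
    a = as_tensor(a)
    return mul(mul(a, 0.5), add(1.0, erf(mul(a, 1.0 / math.sqrt(2.0)))))


def relu(a):
    a = as_tensor(a)
    mask = (a.data > 0).astype(np.float64)
    return _make(a.data * mask, (a,), (lambda g: mul(g, mask),))


# -- backward pass ----------------------------------------------------------

def grad(output, wrt, seed=None):
    """Gradients of ``output`` with respect to the tensors in ``wrt``.

    The returned gradients are themselves graph nodes, so they can be fed
    back into further traced computation (double backprop).

    Parameters
    ----------
    output : Tensor
        Typically a scalar; otherwise ``seed`` must be given.
    wrt : sequence of Tensor
    seed : array-like, optional
        Cotangent to seed the backward pass with (defaults to ones).
    """
    if not isinstance(output, Tensor):
        raise TypeError("output must be a Tensor")
    if seed is None:
        seed = np.ones_like(output.data)

    # iterative topological order
    topo, visiting = [], set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visiting or not node.requires_grad:
            continue
        visiting.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in visiting:
                stack.append((p, False))

    grads = {id(output): as_tensor(seed)}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for p, vjp in zip(node._parents, node._vjps):
            if not p.requires_grad:
                continue
            pg = vjp(g)
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg

    return [grads.get(id(w), Tensor(np.zeros_like(w.data))) for w in wrt]
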