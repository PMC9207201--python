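"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package are tiny (~10^3 parameters), but the
meta-learning outer loop needs gradients *through* an inner gradient
step.  Every vector-Jacobian product here is therefore expressed with
the engine's own operations, so calling :func:`grad` with
``create_graph=True`` on the output of a previous :func:`grad` yields
exact higher-order derivatives (the same mechanism as
``create_graph=True`` in the large frameworks).

Only the operations the package's models need are provided; all data is
float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "grad", "no_grad",
    "add", "sub", "mul", "div", "neg", "pow_const", "exp", "log",
    "matmul", "transpose", "reshape", "tsum", "tmean", "relu",
    "broadcast_to", "take_columns", "scatter_columns",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager: tensors built inside do not record the graph."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array plus the closures needed to backpropagate into it."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad=False, _parents=(), _vjps=()):
        if type(data) is np.ndarray and data.dtype == np.float64:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=np.float64)
        if _GRAD_ENABLED and (
            requires_grad or any(p.requires_grad for p in _parents)
        ):
            self.requires_grad = True
            self._parents = _parents
            self._vjps = _vjps
        else:
            self.requires_grad = requires_grad
            self._parents = ()
            self._vjps = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=self.requires_grad)

    def item(self) -> float:
        return float(self.data)

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    def __radd__(self, other):
        return add(as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    def __rmul__(self, other):
        return mul(as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_const(self, p)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------
# broadcasting helpers


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce g down to `shape` by summing the broadcast axes."""
    if g.data.shape == shape:
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)), keepdims=False)
    axes = tuple(
        i for i, (gs, ss) in enumerate(zip(g.data.shape, shape)) if ss == 1 and gs != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.data.shape != shape:
        g = reshape(g, shape)
    return g


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    return Tensor(
        np.broadcast_to(a.data, shape),
        _parents=(a,),
        _vjps=(lambda g: _unbroadcast(g, old),),
    )


# ---------------------------------------------------------------------
# primitive operations


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _unbroadcast(g, a.data.shape),
            lambda g: _unbroadcast(g, b.data.shape),
        ),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data - b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _unbroadcast(g, a.data.shape),
            lambda g: _unbroadcast(neg(g), b.data.shape),
        ),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _unbroadcast(mul(g, b), a.data.shape),
            lambda g: _unbroadcast(mul(g, a), b.data.shape),
        ),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data / b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _unbroadcast(div(g, b), a.data.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.data.shape),
        ),
    )


def neg(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return Tensor(-a.data, _parents=(a,), _vjps=(lambda g: neg(g),))


def pow_const(a: Tensor, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return Tensor(
        a.data ** p,
        _parents=(a,),
        _vjps=(lambda g: mul(g, mul(Tensor(np.float64(p)), pow_const(a, p - 1.0))),),
    )


def exp(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.exp(a.data), _parents=(a,), _vjps=(lambda g: mul(g, exp(a)),))


def log(a: Tensor) -> Tensor:
    a = as_tensor(a)
    return Tensor(np.log(a.data), _parents=(a,), _vjps=(lambda g: div(g, a),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product."""
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data @ b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: matmul(g, transpose(b)),
            lambda g: matmul(transpose(a), g),
        ),
    )


def transpose(a: Tensor, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.data.ndim)))
    inv = tuple(np.argsort(axes))
    return Tensor(
        np.transpose(a.data, axes),
        _parents=(a,),
        _vjps=(lambda g: transpose(g, inv),),
    )


def reshape(a: Tensor, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    return Tensor(
        np.reshape(a.data, shape),
        _parents=(a,),
        _vjps=(lambda g: reshape(g, old),),
    )


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    if axis is None:
        axes = tuple(range(a.data.ndim))
    elif isinstance(axis, int):
        axes = (axis,)
    else:
        axes = tuple(axis)
    kd_shape = tuple(1 if i in axes else s for i, s in enumerate(old))

    def vjp(g):
        return broadcast_to(reshape(g, kd_shape), old)

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,), _vjps=(vjp,))


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[i] for i in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.float64(1.0 / n)))


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor(a.data * mask.data, _parents=(a,), _vjps=(lambda g: mul(g, mask),))


# ---------------------------------------------------------------------
# column gather / scatter (the im2col primitive pair)

_SCATTER_CACHE: dict[tuple, tuple] = {}


def _inverse_map(cols: np.ndarray, width: int):
    """Precompute, for each output column, the gather positions that map
    into it (padded with a sentinel pointing at an appended zero column)."""
    key = (cols.tobytes(), width)
    cached = _SCATTER_CACHE.get(key)
    if cached is not None:
        return cached
    lists: list[list[int]] = [[] for _ in range(width)]
    for src, dst in enumerate(cols):
        lists[int(dst)].append(src)
    depth = max((len(l) for l in lists), default=1)
    depth = max(depth, 1)
    sentinel = len(cols)
    inv = np.full((width, depth), sentinel, dtype=np.intp)
    for j, l in enumerate(lists):
        inv[j, : len(l)] = l
    flat = inv.ravel()
    _SCATTER_CACHE[key] = (flat, inv.shape, sentinel)
    return flat, inv.shape, sentinel


def take_columns(a: Tensor, cols: np.ndarray) -> Tensor:
    """Gather ``a[:, cols]`` for a 2-D tensor and integer column index.

    The adjoint is :func:`scatter_columns`; the pair is linear, so
    higher-order gradients through it are exact.
    """
    a = as_tensor(a)
    cols = np.asarray(cols, dtype=np.intp)
    width = a.data.shape[1]
    return Tensor(
        a.data[:, cols],
        _parents=(a,),
        _vjps=(lambda g: scatter_columns(g, cols, width),),
    )


def scatter_columns(g: Tensor, cols: np.ndarray, width: int) -> Tensor:
    """Adjoint of :func:`take_columns`: sum g's columns into `width` slots."""
    g = as_tensor(g)
    cols = np.asarray(cols, dtype=np.intp)
    flat, inv_shape, sentinel = _inverse_map(cols, width)
    n = g.data.shape[0]
    padded = np.empty((n, sentinel + 1), dtype=np.float64)
    padded[:, :sentinel] = g.data
    padded[:, sentinel] = 0.0
    out = padded[:, flat].reshape((n,) + inv_shape).sum(axis=2)
    return Tensor(out, _parents=(g,), _vjps=(lambda h: take_columns(h, cols),))


# ---------------------------------------------------------------------


def grad(output: Tensor, inputs, grad_output: Tensor | None = None,
         create_graph: bool = False):
    """Gradients of a scalar (or seeded) output w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves
    graph-connected Tensors and can be differentiated again.
    """
    inputs = list(inputs)
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(output, False)]
    while stack:  # iterative DFS; graphs can exceed the recursion limit
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in visited:
                stack.append((p, False))

    grads: dict[int, Tensor] = {}
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads[id(output)] = grad_output

    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = create_graph
    try:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = add(grads[id(parent)], pg)
                else:
                    grads[id(parent)] = pg
    finally:
        _GRAD_ENABLED = prev

    return [grads.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]
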