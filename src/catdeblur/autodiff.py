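"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine in the spirit of the early
autograd package.  Every operation records its parents and a
vector-Jacobian product (VJP) closure; crucially the VJPs are written in
terms of engine ops themselves, so a gradient obtained with
``grad(..., create_graph=True)`` is again a differentiable graph node.
That second-order capability is what lets the Wasserstein critic's
gradient penalty back-propagate into the critic parameters exactly.

Only the ops needed by the networks in this package are provided:
elementwise arithmetic, matmul, reductions, shape ops, padding,
``im2col``/``col2im`` (the linear kernels behind convolution and
transposed convolution) and a handful of activations.
"""
from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_STACK = [True]


@contextmanager
def no_grad():
    """Disable graph recording inside the context."""
    _GRAD_STACK.append(False)
    try:
        yield
    finally:
        _GRAD_STACK.pop()


def _tracing() -> bool:
    return _GRAD_STACK[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._vjp = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -astensor(other))

    def __rsub__(self, other):
        return add(astensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if _tracing() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


# ---------------------------------------------------------------------
# broadcasting helper: reduce a cotangent back to a parent's shape
# ---------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    if g.shape == tuple(shape):
        return g
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------

def _raw(t: Tensor):
    """0-d operands as python scalars so numpy keeps float32 intact."""
    return t.data.item() if t.data.ndim == 0 else t.data


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(_raw(a) + _raw(b) if a.ndim == 0 or b.ndim == 0 else a.data + b.data,
                 (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return _make(_raw(a) * _raw(b) if a.ndim == 0 or b.ndim == 0 else a.data * b.data,
                 (a, b), vjp)


def power(a, p: float) -> Tensor:
    a = astensor(a)
    p = float(p)

    def vjp(g):
        return (mul(g, mul(power(a, p - 1.0), p)),)

    return _make(a.data ** p, (a,), vjp)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    # the vjp recomputes exp(a) from the parent rather than capturing the
    # output tensor: capturing it would make a reference cycle that keeps
    # whole graphs alive until a gc pass
    a = astensor(a)

    def vjp(g):
        return (mul(g, exp(a)),)

    return _make(np.exp(a.data), (a,), vjp)


def log(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (mul(g, power(a, -1.0)),)

    return _make(np.log(a.data), (a,), vjp)


def tanh(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        y = tanh(a)
        return (mul(g, 1.0 - mul(y, y)),)

    return _make(np.tanh(a.data), (a,), vjp)


def _sigmoid_data(x: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def sigmoid(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        y = sigmoid(a)
        return (mul(g, mul(y, 1.0 - y)),)

    return _make(_sigmoid_data(a.data), (a,), vjp)


def softplus(a) -> Tensor:
    """log(1+exp(x)), numerically stable."""
    a = astensor(a)
    data = np.logaddexp(0.0, a.data)

    def vjp(g):
        return (mul(g, sigmoid(a)),)

    return _make(data, (a,), vjp)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    mask = np.where(a.data >= 0, a.dtype.type(1.0), a.dtype.type(slope))

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return _make(a.data * mask, (a,), vjp)


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


# ---------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis,)
    else:
        axes = tuple(axis)

    def vjp(g):
        if not keepdims and axes:
            shape = list(g.shape)
            for ax in sorted(axes):
                shape.insert(ax if ax >= 0 else ax + a.ndim, 1)
            g = reshape(g, tuple(shape))
        # broadcast back up via an add with zeros of the parent shape
        return (add(g, Tensor(np.zeros(a.shape, dtype=a.dtype))),)

    return _make(a.data.sum(axis=axes if axis is not None else None, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape

    def vjp(g):
        return (reshape(g, old),)

    return _make(a.data.reshape(shape), (a,), vjp)


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return _make(a.data.transpose(axes), (a,), vjp)


def swap_last2(a) -> Tensor:
    a = astensor(a)
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        da = _unbroadcast(matmul(g, swap_last2(b)), a.shape)
        db = _unbroadcast(matmul(swap_last2(a), g), b.shape)
        return da, db

    return _make(np.matmul(a.data, b.data), (a, b), vjp)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for i in range(len(tensors)):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(getslice(g, tuple(key)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def getslice(a, key) -> Tensor:
    a = astensor(a)
    shape = a.shape

    def vjp(g):
        return (putslice(g, key, shape),)

    return _make(a.data[key], (a,), vjp)


def putslice(g, key, shape) -> Tensor:
    """Adjoint of ``getslice``: embed ``g`` into zeros of ``shape``."""
    g = astensor(g)

    def vjp(cot):
        return (getslice(cot, key),)

    out = np.zeros(shape, dtype=g.dtype)
    out[key] = g.data
    return _make(out, (g,), vjp)


def pad_zero(a, pads) -> Tensor:
    """Zero-pad; ``pads`` is a per-axis sequence of (before, after)."""
    a = astensor(a)
    key = tuple(slice(p0, p0 + n) for (p0, _), n in zip(pads, a.shape))

    def vjp(g):
        return (getslice(g, key),)

    return _make(np.pad(a.data, pads), (a,), vjp)


# ---------------------------------------------------------------------
# convolution kernels: im2col / col2im (mutually adjoint linear maps)
# ---------------------------------------------------------------------

def _im2col_data(x: np.ndarray, k: int, s: int) -> np.ndarray:
    B, C, H, W = x.shape
    Ho, Wo = (H - k) // s + 1, (W - k) // s + 1
    out = np.empty((B, C, k, k, Ho, Wo), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            out[:, :, a, b] = x[:, :, a:a + s * Ho:s, b:b + s * Wo:s]
    return out


def _col2im_data(g: np.ndarray, k: int, s: int, H: int, W: int) -> np.ndarray:
    B, C = g.shape[:2]
    Ho, Wo = g.shape[-2:]
    out = np.zeros((B, C, H, W), dtype=g.dtype)
    for a in range(k):
        for b in range(k):
            out[:, :, a:a + s * Ho:s, b:b + s * Wo:s] += g[:, :, a, b]
    return out


def im2col(x, k: int, stride: int) -> Tensor:
    x = astensor(x)
    H, W = x.shape[-2:]

    def vjp(g):
        return (col2im(g, k, stride, H, W),)

    return _make(_im2col_data(x.data, k, stride), (x,), vjp)


def col2im(g, k: int, stride: int, H: int, W: int) -> Tensor:
    g = astensor(g)

    def vjp(cot):
        return (im2col(cot, k, stride),)

    return _make(_col2im_data(g.data, k, stride, H, W), (g,), vjp)


def _im2col_axis_data(x: np.ndarray, k: int, axis: int) -> np.ndarray:
    """1-D sliding windows (stride 1) along ``axis`` (2 or 3) of BCHW."""
    B, C, H, W = x.shape
    if axis == 3:
        Wo = W - k + 1
        out = np.empty((B, C, k, H, Wo), dtype=x.dtype)
        for a in range(k):
            out[:, :, a] = x[:, :, :, a:a + Wo]
    else:
        Ho = H - k + 1
        out = np.empty((B, C, k, Ho, W), dtype=x.dtype)
        for a in range(k):
            out[:, :, a] = x[:, :, a:a + Ho, :]
    return out


def _col2im_axis_data(g: np.ndarray, k: int, axis: int, H: int, W: int) -> np.ndarray:
    B, C = g.shape[:2]
    out = np.zeros((B, C, H, W), dtype=g.dtype)
    if axis == 3:
        Wo = g.shape[-1]
        for a in range(k):
            out[:, :, :, a:a + Wo] += g[:, :, a]
    else:
        Ho = g.shape[-2]
        for a in range(k):
            out[:, :, a:a + Ho, :] += g[:, :, a]
    return out


def im2col_axis(x, k: int, axis: int) -> Tensor:
    x = astensor(x)
    H, W = x.shape[-2:]

    def vjp(g):
        return (col2im_axis(g, k, axis, H, W),)

    return _make(_im2col_axis_data(x.data, k, axis), (x,), vjp)


def col2im_axis(g, k: int, axis: int, H: int, W: int) -> Tensor:
    g = astensor(g)

    def vjp(cot):
        return (im2col_axis(cot, k, axis),)

    return _make(_col2im_axis_data(g.data, k, axis, H, W), (g,), vjp)


# ---------------------------------------------------------------------
# the gradient engine
# ---------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False, cotangent: Tensor | None = None):
    """Cotangents of ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned tensors are themselves graph
    nodes and can be differentiated again.
    """
    if cotangent is None:
        cotangent = Tensor(np.ones_like(output.data))
    cots: dict[int, Tensor] = {id(output): cotangent}
    order = _toposort(output)
    keep = {id(t) for t in inputs}

    def run():
        for node in reversed(order):
            g = cots.get(id(node))
            if g is None or node._vjp is None:
                continue
            parent_gs = node._vjp(g)
            for p, pg in zip(node._parents, parent_gs):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in cots:
                    cots[id(p)] = add(cots[id(p)], pg)
                else:
                    cots[id(p)] = pg
            if id(node) not in keep:
                del cots[id(node)]  # free consumed cotangents promptly

    if create_graph:
        run()
    else:
        with no_grad():
            run()
    return [cots.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]


def backward(loss: Tensor, params) -> None:
    """Accumulate d(loss)/d(param) into each parameter's ``.grad``."""
    gs = grad(loss, list(params))
    for p, g in zip(params, gs):
        if p.grad is None:
            p.grad = np.array(g.data, dtype=p.dtype, copy=True)
        else:
            p.grad += g.data.astype(p.dtype, copy=False)
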