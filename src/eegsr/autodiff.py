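"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape/graph engine: each :class:`Tensor` records the
operation that produced it, and every operation's vector-Jacobian product is
itself expressed in terms of graph operations.  Because backward passes build
new graph nodes, gradients are themselves differentiable, which is what the
Wasserstein critic's gradient penalty needs (the penalty term contains the
critic's input gradient, and its parameter gradient is a second derivative).

Only the primitives the EEG networks require are provided: elementwise
arithmetic, matmul, reductions, reshaping, zero-padding/slicing, patch
extraction (im2col/col2im) and temporal zero-stuffing for fractional-stride
convolutions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "grad"]


class Tensor:
    """A numpy array plus the graph edge that produced it."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, parents=(), vjp=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.vjp = vjp  # callable(grad: Tensor) -> tuple[Tensor | None, ...]
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self.parents
        )

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that optimizers update in place."""

    def __init__(self, data):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce `g` back to `shape`
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    gnd, snd = g.ndim, len(shape)
    if gnd > snd:
        g = tsum(g, axis=tuple(range(gnd - snd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# elementwise primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(a.data + b.data, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return Tensor(a.data * b.data, (a, b), vjp)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)

    def vjp(g):
        return (mul(g, mul(power(a, p - 1.0), p)),)

    return Tensor(a.data**p, (a,), vjp)


def log(a) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        return (mul(g, power(a, -1.0)),)

    return Tensor(np.log(a.data), (a,), vjp)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def vjp(g):
        # rebuild exp(a) as a graph node for higher-order correctness
        return (mul(g, exp(a)),)

    return Tensor(out_data, (a,), vjp)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def vjp(g):
        sg = sigmoid(a)
        return (mul(g, mul(sg, add(1.0, mul(sg, -1.0)))),)

    return Tensor(s, (a,), vjp)


def absolute(a) -> Tensor:
    """|a| with sign(a) as the (a.e. correct) derivative."""
    a = as_tensor(a)
    sgn = np.sign(a.data)

    def vjp(g):
        return (mul(g, Tensor(sgn)),)

    return Tensor(np.abs(a.data), (a,), vjp)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope)

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return Tensor(a.data * mask, (a,), vjp)


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def vjp(g):
        gg = g
        if not keepdims:
            shp = list(a.shape)
            for ax in axes:
                shp[ax] = 1
            gg = reshape(gg, tuple(shp))
        return (broadcast_to(gg, a.shape),)

    return Tensor(a.data.sum(axis=axes, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)

    def vjp(g):
        return (_unbroadcast(g, a.shape),)

    return Tensor(np.broadcast_to(a.data, shape), (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    old = a.shape

    def vjp(g):
        return (reshape(g, old),)

    return Tensor(a.data.reshape(shape), (a,), vjp)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return Tensor(a.data.transpose(axes), (a,), vjp)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            outs.append(getitem(g, tuple(sl)))
        return tuple(outs)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def getitem(a, key) -> Tensor:
    """Basic (slice/int) indexing; gradient scatters back into zeros."""
    a = as_tensor(a)

    def vjp(g):
        return (scatter(g, a.shape, key),)

    return Tensor(a.data[key], (a,), vjp)


def scatter(g, shape, key) -> Tensor:
    """Embed `g` into a zero array of `shape` at `key` (adjoint of getitem)."""
    g = as_tensor(g)

    def vjp(gg):
        return (getitem(gg, key),)

    out = np.zeros(shape, dtype=np.float64)
    out[key] = g.data
    return Tensor(out, (g,), vjp)


def pad2d(a, pad_h: int, pad_w: int) -> Tensor:
    """Zero-pad the last two axes symmetrically."""
    a = as_tensor(a)
    if pad_h == 0 and pad_w == 0:
        return a
    widths = [(0, 0)] * (a.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
    key = tuple(
        [slice(None)] * (a.ndim - 2)
        + [
            slice(pad_h, pad_h + a.shape[-2]),
            slice(pad_w, pad_w + a.shape[-1]),
        ]
    )

    def vjp(g):
        return (getitem(g, key),)

    return Tensor(np.pad(a.data, widths), (a,), vjp)


# ---------------------------------------------------------------------------
# convolution support: im2col / col2im over the trailing two axes
# ---------------------------------------------------------------------------


def _conv_geometry(H, W, kh, kw, sh, sw):
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    return Ho, Wo


def _im2col_data(x, kh, kw, sh, sw):
    B, C, H, W = x.shape
    Ho, Wo = _conv_geometry(H, W, kh, kw, sh, sw)
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw, :, :]  # (B, C, Ho, Wo, kh, kw)
    col = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, Ho * Wo)
    return np.ascontiguousarray(col)


def _col2im_data(col, x_shape, kh, kw, sh, sw):
    B, C, H, W = x_shape
    Ho, Wo = _conv_geometry(H, W, kh, kw, sh, sw)
    col = col.reshape(B, C, kh, kw, Ho, Wo)
    out = np.zeros(x_shape, dtype=np.float64)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += col[:, :, i, j]
    return out


def im2col(x, kh, kw, sh=1, sw=1) -> Tensor:
    """(B, C, H, W) -> (B, C*kh*kw, Ho*Wo) patch matrix (linear gather)."""
    x = as_tensor(x)
    shape = x.shape

    def vjp(g):
        return (col2im(g, shape, kh, kw, sh, sw),)

    return Tensor(_im2col_data(x.data, kh, kw, sh, sw), (x,), vjp)


def col2im(col, x_shape, kh, kw, sh=1, sw=1) -> Tensor:
    """Adjoint of :func:`im2col` (linear scatter-add)."""
    col = as_tensor(col)
    x_shape = tuple(x_shape)

    def vjp(g):
        return (im2col(g, kh, kw, sh, sw),)

    return Tensor(_col2im_data(col.data, x_shape, kh, kw, sh, sw), (col,), vjp)


def zero_stuff(a, factor: int) -> Tensor:
    """Insert `factor-1` zeros between samples along the last axis."""
    a = as_tensor(a)
    shape = a.shape[:-1] + (a.shape[-1] * factor,)
    key = tuple([slice(None)] * (a.ndim - 1) + [slice(0, None, factor)])

    def vjp(g):
        return (getitem(g, key),)

    out = np.zeros(shape, dtype=np.float64)
    out[key] = a.data
    return Tensor(out, (a,), vjp)


# ---------------------------------------------------------------------------
# matmul (supports (..., n, k) @ (..., k, m) with numpy broadcasting)
# ---------------------------------------------------------------------------


def _swap_last(t: Tensor) -> Tensor:
    axes = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return transpose(t, axes)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = gb = None
        if a.ndim >= 2 and b.ndim >= 2:
            ga = _unbroadcast(matmul(g, _swap_last(b)), a.shape)
            gb = _unbroadcast(matmul(_swap_last(a), g), b.shape)
        else:  # 1-D operands are not needed by the networks
            raise NotImplementedError("matmul grad requires >=2-D operands")
        return ga, gb

    return Tensor(np.matmul(a.data, b.data), (a, b), vjp)


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------


def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children appear after parents


def grad(output: Tensor, wrt, grad_output=None):
    """Gradients of scalar `output` w.r.t. each tensor in `wrt`.

    The returned gradients are themselves graph tensors, so they can be fed
    into further computation and differentiated again.
    """
    if isinstance(wrt, Tensor):
        wrt = [wrt]
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): as_tensor(grad_output)}
    for node in reversed(_topo(output)):
        g = grads.pop(id(node), None)
        if g is None or node.vjp is None:
            if g is not None:
                grads[id(node)] = g  # leaf: keep
            continue
        parent_grads = node.vjp(g)
        for p, pg in zip(node.parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg
        grads[id(node)] = g  # retain for wrt lookups on interior nodes
    out = []
    for t in wrt:
        gt = grads.get(id(t))
        out.append(gt if gt is not None else Tensor(np.zeros_like(t.data)))
    return out
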