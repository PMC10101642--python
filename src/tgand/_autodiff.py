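"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The WGAN-GP critic objective contains the norm of the critic's *input*
gradient, so optimising it requires differentiating through a gradient —
double backpropagation.  Every primitive therefore implements its
vector-Jacobian products (VJPs) in terms of other primitives: the backward
pass builds an ordinary graph, and :func:`grad` with ``create_graph=True``
can be differentiated again to any order.

Only the operations the package's networks need are provided: elementwise
arithmetic, matmul, reductions, shape ops, a closed family of convolution
primitives (forward / input-gradient / weight-gradient, which are each
other's adjoints), embedding lookup, and the usual activations.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "grad",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "reshape",
    "transpose",
    "broadcast_to",
    "tsum",
    "tmean",
    "power",
    "sqrt",
    "exp",
    "log",
    "tanh",
    "leaky_relu",
    "relu",
    "concat",
    "narrow",
    "index_rows",
    "conv2d",
    "conv2d_input_grad",
    "conv2d_weight_grad",
    "batch_norm",
    "softmax_cross_entropy",
    "softmax",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjps: tuple = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjps) -> Tensor:
    """Create an op output; record the graph only when tracking is on.

    Fast path: primitives always hand in a float ndarray, so the
    :class:`Tensor` constructor's coercion is skipped.
    """
    requires = False
    if _GRAD_ENABLED:
        for p in parents:
            if p.requires_grad:
                requires = True
                break
    out = Tensor.__new__(Tensor)
    out.data = data
    out.requires_grad = requires
    if requires:
        out._parents = tuple(parents)
        out._vjps = tuple(vjps)
    else:
        out._parents = ()
        out._vjps = ()
    return out


# ---------------------------------------------------------------------------
# shape helpers
# ---------------------------------------------------------------------------


def _sum_to(g: Tensor, shape) -> Tensor:
    """Reduce a broadcast cotangent back to ``shape``."""
    if g.shape == tuple(shape):
        return g
    lead = g.ndim - len(shape)
    axes = tuple(range(lead))
    axes += tuple(
        i + lead for i, s in enumerate(shape) if s == 1 and g.shape[i + lead] != 1
    )
    out = tsum(g, axis=axes, keepdims=False) if axes else g
    return reshape(out, tuple(shape))


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(g, b.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data - b.data,
        (a, b),
        (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(neg(g), b.shape)),
    )


def neg(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(-a.data, (a,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        (lambda g: _sum_to(mul(g, b), a.shape), lambda g: _sum_to(mul(g, a), b.shape)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data / b.data,
        (a, b),
        (
            lambda g: _sum_to(div(g, b), a.shape),
            lambda g: _sum_to(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def power(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    return _node(
        a.data**p,
        (a,),
        (lambda g: mul(g, mul(Tensor(np.asarray(p, dtype=a.dtype)), power(a, p - 1.0))),),
    )


def sqrt(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def vjp(g, out_data=out_data):
        return div(mul(g, Tensor(np.asarray(0.5, dtype=g.dtype))), Tensor(out_data))

    # NB: treating sqrt(a) as constant in the VJP would break double backprop;
    # express it through power instead.
    return _node(out_data, (a,), (lambda g: mul(g, mul(Tensor(np.asarray(0.5, dtype=a.dtype)), power(a, -0.5))),))


def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(np.exp(a.data), (a,), (lambda g: mul(g, exp(a)),))


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(np.log(a.data), (a,), (lambda g: div(g, a),))


def tanh(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(
        np.tanh(a.data),
        (a,),
        (lambda g: mul(g, sub(Tensor(np.asarray(1.0, dtype=a.dtype)), mul(tanh(a), tanh(a)))),),
    )


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
    return _node(a.data * mask, (a,), (lambda g: mul(g, Tensor(mask)),))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    shape = tuple(shape)
    in_shape = a.shape
    return _node(
        a.data.reshape(shape), (a,), (lambda g: reshape(g, in_shape),)
    )


def transpose(a: Tensor, axes=None) -> Tensor:
    a = _as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(
        a.data.transpose(axes), (a,), (lambda g: transpose(g, inv),)
    )


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    shape = tuple(shape)
    in_shape = a.shape
    return _node(
        np.broadcast_to(a.data, shape).copy(),
        (a,),
        (lambda g: _sum_to(g, in_shape),),
    )


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    in_shape = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def vjp(g):
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
            g = reshape(g, kshape)
        return broadcast_to(g, in_shape)

    return _node(a.data.sum(axis=axes, keepdims=keepdims), (a,), (vjp,))


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    vjps = []
    for i in range(len(tensors)):
        start, length = int(offsets[i]), int(sizes[i])
        vjps.append(lambda g, s=start, ln=length: narrow(g, axis, s, ln))
    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), tuple(vjps))


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    a = _as_tensor(a)
    axis = axis % a.ndim
    total = a.shape[axis]
    idx = tuple(
        slice(start, start + length) if i == axis else slice(None) for i in range(a.ndim)
    )
    return _node(
        a.data[idx].copy(),
        (a,),
        (lambda g: _pad_zeros(g, axis, start, total),),
    )


def _pad_zeros(a: Tensor, axis: int, start: int, total: int) -> Tensor:
    a = _as_tensor(a)
    length = a.shape[axis]
    pad = [(0, 0)] * a.ndim
    pad[axis] = (start, total - start - length)
    return _node(
        np.pad(a.data, pad),
        (a,),
        (lambda g: narrow(g, axis, start, length),),
    )


def index_rows(table: Tensor, idx) -> Tensor:
    """Row lookup ``table[idx]`` (embedding); adjoint is scatter-add."""
    table = _as_tensor(table)
    idx = np.asarray(idx, dtype=np.int64)
    nrows = table.shape[0]
    return _node(
        table.data[idx],
        (table,),
        (lambda g: _scatter_rows(g, idx, nrows),),
    )


def _scatter_rows(g: Tensor, idx, nrows: int) -> Tensor:
    g = _as_tensor(g)
    out = np.zeros((nrows,) + g.shape[1:], dtype=g.dtype)
    np.add.at(out, idx, g.data)
    return _node(out, (g,), (lambda u: index_rows(u, idx),))


# ---------------------------------------------------------------------------
# matmul
# ---------------------------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product (all the dense layers need)."""
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data @ b.data,
        (a, b),
        (
            lambda g: matmul(g, transpose(b)),
            lambda g: matmul(transpose(a), g),
        ),
    )


# ---------------------------------------------------------------------------
# convolution family
#
# With T(x, w, g) = <conv2d(x, w), g> trilinear, the three ops
#   conv2d(x, w)              : (N,C,H,W) x (F,C,k,k) -> (N,F,Ho,Wo)
#   conv2d_input_grad(g, w)   : adjoint w.r.t. x  (also used as the forward
#                               pass of stride-2 transposed convolution)
#   conv2d_weight_grad(x, g)  : adjoint w.r.t. w
# are closed under differentiation: every VJP is again one of the three.
# ---------------------------------------------------------------------------


def _conv_out_hw(h, w, k, s, p):
    return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho, wo = _conv_out_hw(h, w, k, s, p)
    sn, sc, sh, sw = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * s, sw * s),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, x_shape, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    ho, wo = _conv_out_hw(h, w, k, s, p)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        hi = i + s * ho
        for j in range(k):
            wj = j + s * wo
            xp[:, :, i:hi:s, j:wj:s] += cols[:, :, i, j]
    if p:
        return xp[:, :, p:-p, p:-p]
    return xp


def _conv2d_np(x, w, s, p, cols=None):
    n = x.shape[0]
    f, c, k, _ = w.shape
    ho, wo = _conv_out_hw(x.shape[2], x.shape[3], k, s, p)
    if cols is None:
        cols = _im2col(x, k, s, p)
    out = np.matmul(w.reshape(f, -1)[None], cols)  # (N, F, L)
    return out.reshape(n, f, ho, wo)


def _conv2d_dx_np(g, w, s, p, x_shape):
    n = g.shape[0]
    f, c, k, _ = w.shape
    gm = g.reshape(n, f, -1)
    cols = np.matmul(w.reshape(f, -1).T[None], gm)  # (N, Ckk, L)
    return _col2im(cols, x_shape, k, s, p)


def _conv2d_dw_np(x, g, s, p, w_shape, cols=None):
    f, c, k, _ = w_shape
    n = x.shape[0]
    if cols is None:
        cols = _im2col(x, k, s, p)  # (N, Ckk, L)
    gm = g.reshape(n, f, -1)
    dw = np.einsum("nfl,ncl->fc", gm, cols, optimize=True)
    return dw.reshape(w_shape)


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    x, w = _as_tensor(x), _as_tensor(w)
    x_shape, w_shape = x.shape, w.shape
    k = w_shape[2]
    cols = _im2col(x.data, k, stride, padding)
    return _node(
        _conv2d_np(x.data, w.data, stride, padding, cols=cols),
        (x, w),
        (
            lambda g: conv2d_input_grad(g, w, stride, padding, x_shape),
            # reuse the forward's patch matrix for the weight-gradient value
            lambda g: conv2d_weight_grad(x, g, stride, padding, w_shape, _cols=cols),
        ),
    )


def conv2d_input_grad(g: Tensor, w: Tensor, stride: int, padding: int, x_shape) -> Tensor:
    g, w = _as_tensor(g), _as_tensor(w)
    x_shape = tuple(x_shape)
    w_shape = w.shape
    return _node(
        _conv2d_dx_np(g.data, w.data, stride, padding, x_shape),
        (g, w),
        (
            lambda u: conv2d(u, w, stride, padding),
            lambda u: conv2d_weight_grad(u, g, stride, padding, w_shape),
        ),
    )


def conv2d_weight_grad(x: Tensor, g: Tensor, stride: int, padding: int, w_shape,
                       _cols=None) -> Tensor:
    x, g = _as_tensor(x), _as_tensor(g)
    w_shape = tuple(w_shape)
    x_shape = x.shape
    return _node(
        _conv2d_dw_np(x.data, g.data, stride, padding, w_shape, cols=_cols),
        (x, g),
        (
            lambda u: conv2d_input_grad(g, u, stride, padding, x_shape),
            lambda u: conv2d(x, u, stride, padding),
        ),
    )


# ---------------------------------------------------------------------------
# fused batch normalisation
# ---------------------------------------------------------------------------


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused batch normalisation over axes (0, 2, 3) of an NCHW tensor.

    Returns ``(out, batch_mean, batch_var)`` with the statistics as plain
    arrays.  The VJP is the closed-form batch-norm backward written in raw
    NumPy: first-order only (it raises under ``create_graph``), which is
    all the generator — the only network using normalisation — requires.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 2, 3)
    m = x.shape[0] * x.shape[2] * x.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (1, -1, 1, 1)
    out_data = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)

    def _first_order(g: Tensor):
        if g.requires_grad:
            raise NotImplementedError(
                "batch_norm supports first-order gradients only"
            )
        return g.data

    def vjp_x(g):
        gd = _first_order(g)
        dxhat = gd * gamma.data.reshape(gshape)
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        dx = (inv / m) * (m * dxhat - s1 - xhat * s2)
        return Tensor(dx.astype(x.dtype, copy=False))

    def vjp_gamma(g):
        gd = _first_order(g)
        return Tensor((gd * xhat).sum(axis=axes).astype(gamma.dtype, copy=False))

    def vjp_beta(g):
        gd = _first_order(g)
        return Tensor(gd.sum(axis=axes).astype(beta.dtype, copy=False))

    out = _node(out_data.astype(x.dtype, copy=False), (x, gamma, beta),
                (vjp_x, vjp_gamma, vjp_beta))
    return out, mu.reshape(-1), var.reshape(-1)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    logits = _as_tensor(logits)
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))  # constant shift
    z = sub(logits, shift)
    e = exp(z)
    return div(e, tsum(e, axis=axis, keepdims=True))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (N, C)."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n, c = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = sub(logits, shift)
    lse = log(tsum(exp(z), axis=1, keepdims=True))
    logp = sub(z, lse)
    onehot = np.zeros((n, c), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    picked = tsum(mul(logp, Tensor(onehot)))
    return mul(picked, Tensor(np.asarray(-1.0 / n, dtype=logits.dtype)))


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------


def grad(output: Tensor, inputs, create_graph: bool = False, grad_output=None):
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes and can be differentiated again (needed for the gradient penalty).
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    # iterative topological sort over the requires_grad subgraph
    topo, state = [], {}
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if not node.requires_grad:
            continue
        if processed:
            topo.append(node)
            continue
        if state.get(id(node)):
            continue
        state[id(node)] = True
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads = {id(output): grad_output}

    def run():
        for node in reversed(topo):
            g = grads.pop(id(node), None)
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
            grads[id(node)] = g  # keep for inputs that are interior nodes

    if create_graph:
        run()
    else:
        with no_grad():
            run()

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out
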