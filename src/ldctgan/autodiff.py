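"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine, written so that every vector-Jacobian
product is itself expressed in terms of the engine's own primitives.  Because
backward passes build new graph nodes, gradients are themselves differentiable
— ``grad(..., create_graph=True)`` supports the double backpropagation needed
to train a critic through a gradient-penalty term.

Everything is CPU-resident numpy (float64 by default, switchable).  The op
set is exactly what a small convolutional GAN needs: broadcasting
arithmetic, reductions, reshapes, gather/scatter, strided im2col/col2im
with a 2-D GEMM family (convolution is one matmul on the column matrix),
and a handful of pointwise nonlinearities.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_DTYPE = np.dtype(np.float64)


def set_default_dtype(dt) -> None:
    """Set the engine-wide element type (float64 by default; float32 trades
    precision for speed in long training runs)."""
    global _DTYPE
    _DTYPE = np.dtype(dt)


def get_default_dtype():
    return _DTYPE


@contextmanager
def default_dtype(dt):
    old = _DTYPE
    set_default_dtype(dt)
    try:
        yield
    finally:
        set_default_dtype(old)

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "add", "sub", "mul", "div", "neg", "pow_const", "sqrt", "exp", "log",
    "relu", "sigmoid", "tanh", "absolute", "clip01",
    "tsum", "tmean", "tmax_axis",
    "reshape", "broadcast_to", "concat", "slice_axis",
    "einsum2", "take_ax1", "scatter_ax1", "pad2d", "crop2d",
    "conv2d", "linear", "unfold",
]


class Tensor:
    """A numpy array plus the tape bookkeeping for reverse-mode AD."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._vjps = vjps

    # -- convenience ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_const(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjps) -> Tensor:
    """Create an op result; prune the tape when no parent needs gradients."""
    track = any(p.requires_grad for p in parents)
    if not track:
        return Tensor(data)
    keep_p, keep_v = [], []
    for p, v in zip(parents, vjps):
        if p.requires_grad:
            keep_p.append(p)
            keep_v.append(v)
    return Tensor(data, requires_grad=True, parents=tuple(keep_p), vjps=tuple(keep_v))


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a gradient back to ``shape`` after numpy-style broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, d in enumerate(shape) if d == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(a.data + b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.shape),
                  lambda g: _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(a.data - b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.shape),
                  lambda g: _unbroadcast(neg(g), b.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(a.data * b.data, (a, b),
                 (lambda g: _unbroadcast(mul(g, b), a.shape),
                  lambda g: _unbroadcast(mul(g, a), b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(_wrap(a), pow_const(_wrap(b), -1.0))


def neg(a: Tensor) -> Tensor:
    a = _wrap(a)
    return _make(-a.data, (a,), (lambda g: neg(g),))


def pow_const(a: Tensor, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)
    return _make(a.data ** p, (a,),
                 (lambda g: mul(g, mul(Tensor(np.float64(p)), pow_const(a, p - 1.0))),))


def sqrt(a: Tensor) -> Tensor:
    return pow_const(a, 0.5)


def exp(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), ())
    if out.requires_grad:
        out._parents = (a,)
        out._vjps = (lambda g: mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    a = _wrap(a)
    return _make(np.log(a.data), (a,), (lambda g: div(g, a),))


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = (a.data > 0).astype(a.data.dtype)
    return _make(a.data * mask, (a,), (lambda g: mul(g, Tensor(mask)),))


def sigmoid(a: Tensor) -> Tensor:
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(s, (a,), ())
    if out.requires_grad:
        out._parents = (a,)
        out._vjps = (lambda g: mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def tanh(a: Tensor) -> Tensor:
    a = _wrap(a)
    t = np.tanh(a.data)
    out = _make(t, (a,), ())
    if out.requires_grad:
        out._parents = (a,)
        out._vjps = (lambda g: mul(g, sub(Tensor(1.0), mul(out, out))),)
    return out


def absolute(a: Tensor) -> Tensor:
    a = _wrap(a)
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (a,), (lambda g: mul(g, Tensor(sign)),))


def clip01(a: Tensor) -> Tensor:
    """Clip to [0, 1]; gradient passes only where the input is interior."""
    a = _wrap(a)
    mask = ((a.data >= 0.0) & (a.data <= 1.0)).astype(a.data.dtype)
    return _make(np.clip(a.data, 0.0, 1.0), (a,), (lambda g: mul(g, Tensor(mask)),))


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g: Tensor) -> Tensor:
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.ndim for ax in axes)
        if keepdims:
            gk = g
        else:
            kshape = tuple(1 if i in axes else d for i, d in enumerate(a.shape))
            gk = reshape(g, kshape)
        return broadcast_to(gk, a.shape)

    return _make(out_data, (a,), (vjp,))


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def tmax_axis(a: Tensor, axis: int) -> Tensor:
    """Max along one axis; ties share the gradient equally."""
    a = _wrap(a)
    out_data = a.data.max(axis=axis)
    expanded = np.expand_dims(out_data, axis)
    mask = (a.data == expanded).astype(a.data.dtype)
    mask /= mask.sum(axis=axis, keepdims=True)

    def vjp(g: Tensor) -> Tensor:
        kshape = list(a.shape)
        kshape[axis % a.ndim] = 1
        return mul(broadcast_to(reshape(g, tuple(kshape)), a.shape), Tensor(mask))

    return _make(out_data, (a,), (vjp,))


def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    shape = tuple(shape)
    old = a.shape
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, old),))


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    shape = tuple(shape)
    return _make(np.broadcast_to(a.data, shape).copy(), (a,),
                 (lambda g: _unbroadcast(g, a.shape),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])

    def make_vjp(i):
        lo, hi = int(offsets[i]), int(offsets[i + 1])
        return lambda g: slice_axis(g, axis, lo, hi)

    return _make(out_data, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def slice_axis(a: Tensor, axis: int, lo: int, hi: int) -> Tensor:
    a = _wrap(a)
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(lo, hi)
    idx = tuple(idx)
    shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        pads = [(0, 0)] * a.ndim
        pads[axis] = (lo, shape[axis] - hi)
        return pad_nd(g, pads)

    return _make(a.data[idx], (a,), (vjp,))


def pad_nd(a: Tensor, pads) -> Tensor:
    a = _wrap(a)
    pads = [tuple(p) for p in pads]

    def vjp(g: Tensor) -> Tensor:
        out = g
        for ax, (lo, hi) in enumerate(pads):
            if lo or hi:
                out = slice_axis(out, ax, lo, out.shape[ax] - hi)
        return out

    return _make(np.pad(a.data, pads), (a,), (vjp,))


def replicate_pad2d(a: Tensor, pad: int) -> Tensor:
    """Edge-replicating pad of the two trailing axes, built from the gather
    primitive so its adjoint (scatter-add onto edge pixels) is exact."""
    if pad == 0:
        return _wrap(a)
    a = _wrap(a)
    *lead, h, w = a.shape
    rows = np.clip(np.arange(-pad, h + pad), 0, h - 1)
    cols = np.clip(np.arange(-pad, w + pad), 0, w - 1)
    idx = rows[:, None] * w + cols[None, :]
    lead_n = int(np.prod(lead)) if lead else 1
    flat = reshape(a, (lead_n, h * w))
    out = take_ax1(flat, idx)
    return reshape(out, tuple(lead) + (h + 2 * pad, w + 2 * pad))


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing (spatial) axes symmetrically."""
    if pad == 0:
        return _wrap(a)
    a = _wrap(a)
    pads = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    return pad_nd(a, pads)


def crop2d(a: Tensor, pad: int) -> Tensor:
    if pad == 0:
        return _wrap(a)
    a = _wrap(a)
    out = slice_axis(a, a.ndim - 2, pad, a.shape[-2] - pad)
    return slice_axis(out, a.ndim - 1, pad, a.shape[-1] - pad)


# ---------------------------------------------------------------------------
# contraction / gather-scatter
# ---------------------------------------------------------------------------

def einsum2(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum.  Every index of each operand must occur in the
    output or in the other operand (true for all matmul-like contractions),
    which makes the VJPs einsums of the same family."""
    a, b = _wrap(a), _wrap(b)
    ins, out_sub = spec.split("->")
    in_a, in_b = ins.split(",")
    out_data = np.einsum(spec, a.data, b.data, optimize=True)
    return _make(
        out_data, (a, b),
        (lambda g: einsum2(f"{out_sub},{in_b}->{in_a}", g, b),
         lambda g: einsum2(f"{in_a},{out_sub}->{in_b}", a, g)))


def transpose2(a: Tensor) -> Tensor:
    a = _wrap(a)
    return _make(a.data.T.copy(), (a,), (lambda g: transpose2(g),))


# 2-D GEMM family: plain, a@b.T and a.T@b variants so that every VJP is a
# single BLAS call on views, never an explicit transposed copy.

def mm2d(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(np.dot(a.data, b.data), (a, b),
                 (lambda g: mm2d_nt(g, b), lambda g: mm2d_tn(a, g)))


def mm2d_nt(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(np.dot(a.data, b.data.T), (a, b),
                 (lambda g: mm2d(g, b), lambda g: mm2d_tn(g, a)))


def mm2d_tn(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _make(np.dot(a.data.T, b.data), (a, b),
                 (lambda g: mm2d_nt(b, g), lambda g: mm2d(a, g)))


def take_ax1(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather ``a[:, idx]`` for 2-D ``a``; the workhorse behind im2col."""
    a = _wrap(a)
    m = a.shape[1]
    return _make(a.data[:, idx], (a,), (lambda g: scatter_ax1(g, idx, m),))


def scatter_ax1(g: Tensor, idx: np.ndarray, m: int) -> Tensor:
    """Adjoint of take_ax1: scatter-add columns back into width ``m``."""
    g = _wrap(g)
    b = g.shape[0]
    flat_idx = idx.reshape(-1)
    out_data = np.zeros((b, m), dtype=g.data.dtype)
    np.add.at(out_data, (slice(None), flat_idx), g.data.reshape(b, -1))
    return _make(out_data, (g,), (lambda gg: take_ax1(gg, idx),))


# ---------------------------------------------------------------------------
# neural-net building blocks
# ---------------------------------------------------------------------------

def _unfold_raw(xp: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Strided-view im2col on a padded (B, C, Hp, Wp) array -> contiguous
    (B, C*k*k, OH*OW) copy."""
    b, c, hp, wp = xp.shape
    eff = (k - 1) * dilation + 1
    oh, ow = hp - eff + 1, wp - eff + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("kernel larger than (padded) input")
    sb, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(b, c, k, k, oh, ow),
        strides=(sb, sc, sh * dilation, sw * dilation, sh, sw))
    return view.reshape(b, c * k * k, oh * ow)


def _fold_raw(g: np.ndarray, shape, k: int, dilation: int) -> np.ndarray:
    """Adjoint of _unfold_raw: overlap-add columns back onto (B, C, Hp, Wp).
    k*k vectorized slice-adds instead of a scattered add."""
    b, c, hp, wp = shape
    eff = (k - 1) * dilation + 1
    oh, ow = hp - eff + 1, wp - eff + 1
    g6 = g.reshape(b, c, k, k, oh, ow)
    out = np.zeros(shape, dtype=g.dtype)
    for ki in range(k):
        ri = ki * dilation
        for kj in range(k):
            cj = kj * dilation
            out[:, :, ri:ri + oh, cj:cj + ow] += g6[:, :, ki, kj]
    return out


def unfold_padded(xp: Tensor, k: int, dilation: int = 1) -> Tensor:
    """im2col primitive on an already padded (B, C, Hp, Wp) tensor."""
    xp = _wrap(xp)
    shape = xp.shape
    return _make(_unfold_raw(xp.data, k, dilation), (xp,),
                 (lambda g: fold_padded(g, shape, k, dilation),))


def fold_padded(g: Tensor, shape, k: int, dilation: int = 1) -> Tensor:
    """col2im primitive (adjoint of unfold_padded); linear, so its own
    adjoint is unfold_padded again."""
    g = _wrap(g)
    return _make(_fold_raw(g.data, tuple(shape), k, dilation), (g,),
                 (lambda gg: unfold_padded(gg, k, dilation),))


def unfold(x: Tensor, k: int, pad: int = 0, dilation: int = 1) -> Tensor:
    """im2col: (B, C, H, W) -> (B, C*k*k, OH*OW), stride 1."""
    x = _wrap(x)
    return unfold_padded(pad2d(x, pad), k, dilation)


def _strided_view(xp: np.ndarray, k: int, dilation: int):
    b, c, hp, wp = xp.shape
    eff = (k - 1) * dilation + 1
    oh, ow = hp - eff + 1, wp - eff + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("kernel larger than (padded) input")
    sb, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(b, c, k, k, oh, ow),
        strides=(sb, sc, sh * dilation, sw * dilation, sh, sw))
    return view, oh, ow


def unfold_km(xp: Tensor, k: int, dilation: int = 1) -> Tensor:
    """im2col in GEMM-major layout: padded (B,C,Hp,Wp) -> (C*k*k, B*OH*OW)."""
    xp = _wrap(xp)
    shape = xp.shape
    view, oh, ow = _strided_view(xp.data, k, dilation)
    cols = view.transpose(1, 2, 3, 0, 4, 5).reshape(
        shape[1] * k * k, shape[0] * oh * ow)
    return _make(cols, (xp,), (lambda g: fold_km(g, shape, k, dilation),))


def fold_km(g: Tensor, shape, k: int, dilation: int = 1) -> Tensor:
    """Overlap-add adjoint of unfold_km."""
    g = _wrap(g)
    b, c, hp, wp = shape
    eff = (k - 1) * dilation + 1
    oh, ow = hp - eff + 1, wp - eff + 1
    g6 = g.data.reshape(c, k, k, b, oh, ow)
    out = np.zeros((c, b, hp, wp), dtype=g.data.dtype)
    for ki in range(k):
        ri = ki * dilation
        for kj in range(k):
            cj = kj * dilation
            out[:, :, ri:ri + oh, cj:cj + ow] += g6[:, ki, kj]
    return _make(np.ascontiguousarray(out.transpose(1, 0, 2, 3)), (g,),
                 (lambda gg: unfold_km(gg, k, dilation),))


def to_bchw(x2: Tensor, b: int, o: int, oh: int, ow: int) -> Tensor:
    """(O, B*OH*OW) GEMM output -> (B, O, OH, OW) feature map."""
    x2 = _wrap(x2)
    out = np.ascontiguousarray(
        x2.data.reshape(o, b, oh * ow).transpose(1, 0, 2)).reshape(b, o, oh, ow)
    return _make(out, (x2,), (lambda g: from_bchw(g),))


def from_bchw(g: Tensor) -> Tensor:
    """(B, O, OH, OW) -> (O, B*OH*OW); adjoint of to_bchw."""
    g = _wrap(g)
    b, o, oh, ow = g.shape
    out = np.ascontiguousarray(
        g.data.reshape(b, o, oh * ow).transpose(1, 0, 2)).reshape(o, b * oh * ow)
    return _make(out, (g,), (lambda gg: to_bchw(gg, b, o, oh, ow),))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           pad: int = 0, dilation: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout.

    Implemented as gather (im2col) + einsum, so parameter and input gradients
    — and their gradients — all flow through differentiable primitives.
    """
    x, weight = _wrap(x), _wrap(weight)
    b, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    if kh != kw:
        raise ValueError("square kernels only")
    cols = unfold_km(pad2d(x, pad), kh, dilation)              # (C*k*k, B*L)
    wf = reshape(weight, (o, c * kh * kw))
    eff_k = (kh - 1) * dilation + 1
    oh = h + 2 * pad - eff_k + 1
    ow = w + 2 * pad - eff_k + 1
    out = to_bchw(mm2d(wf, cols), b, o, oh, ow)
    if bias is not None:
        out = add(out, reshape(_wrap(bias), (1, o, 1, 1)))
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """(B, F) @ (O, F)^T + bias."""
    out = mm2d_nt(_wrap(x), _wrap(weight))
    if bias is not None:
        bias = _wrap(bias)
        out = add(out, reshape(bias, (1, bias.shape[0])))
    return out


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------

def grad(out: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar ``out`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own tape,
    enabling higher-order differentiation (double backprop).
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    if out.size != 1:
        raise ValueError("grad expects a scalar output")

    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(out, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in visited:
                stack.append((p, False))

    grads: dict[int, Tensor] = {id(out): Tensor(np.ones_like(out.data))}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for p, vjp in zip(node._parents, node._vjps):
            contrib = vjp(g)
            prev = grads.get(id(p))
            grads[id(p)] = contrib if prev is None else add(prev, contrib)

    results = []
    for x in inputs:
        gx = grads.get(id(x))
        if gx is None:
            gx = Tensor(np.zeros_like(x.data))
        elif not create_graph:
            gx = gx.detach()
        results.append(gx)
    return results[0] if single else results
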