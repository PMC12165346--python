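"""Minimal reverse-mode automatic differentiation with higher-order support.

The episodic meta-learner needs gradients of gradients: the outer-loop
update differentiates the query loss through the inner-loop adaptation
steps. No autodiff framework is available in the target environment, so
this module provides a small tape-based engine over numpy arrays in the
style of HIPS autograd: every primitive's vector-Jacobian product is itself
expressed in terms of traced primitives, so ``grad(..., create_graph=True)``
yields a differentiable graph and arbitrary-order derivatives come for free.

Only the primitives the base networks need are implemented: elementwise
arithmetic, matmul, reductions, indexing/scatter, padding and im2col/col2im
(convolution is composed as im2col + matmul, which keeps double-backprop
correct by construction).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "grad",
    "add", "sub", "mul", "div", "neg", "pow_", "exp", "log", "sqrt", "tanh",
    "relu", "matmul", "gsum", "gmean", "gmax", "reshape", "swapaxes",
    "broadcast_to", "getitem", "pad2d", "im2col", "col2im", "stop_gradient",
    "softmax", "log_softmax", "cross_entropy", "dropout",
    "conv2d", "maxpool2x2", "batchnorm", "layernorm", "linear",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape edges that produced it."""

    __slots__ = ("data", "parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        if isinstance(data, np.ndarray):
            self.data = data
        else:
            arr = np.asarray(data)
            if not np.issubdtype(arr.dtype, np.floating):
                arr = arr.astype(np.float64)
            self.data = arr
        self.parents = tuple(parents)
        self.requires_grad = bool(requires_grad)

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

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return gsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return gmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _node(data: np.ndarray, parents) -> Tensor:
    if not _GRAD_ENABLED:
        return Tensor(data)
    parents = tuple((p, vjp) for p, vjp in parents if p.requires_grad)
    return Tensor(data, requires_grad=bool(parents), parents=parents)


def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce a broadcast gradient back to ``shape`` (traced)."""
    while g.ndim > len(shape):
        g = gsum(g, axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = gsum(g, axis=axes, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------
# Python scalars take a fast path that keeps them off the tape and, under
# numpy's weak promotion, preserves float32 parameter dtypes.

def _is_scalar(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def add(a, b) -> Tensor:
    if _is_scalar(b):
        a = _as_tensor(a)
        return _node(a.data + b, [(a, lambda g: g)])
    if _is_scalar(a):
        return add(b, a)
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data + b.data, [
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ])


def sub(a, b) -> Tensor:
    if _is_scalar(b):
        return add(a, -b)
    if _is_scalar(a):
        return add(neg(b), a)
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data - b.data, [
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(neg(g), b.shape)),
    ])


def neg(a) -> Tensor:
    a = _as_tensor(a)
    return _node(-a.data, [(a, lambda g: neg(g))])


def mul(a, b) -> Tensor:
    if _is_scalar(b):
        a = _as_tensor(a)
        return _node(a.data * b, [(a, lambda g: mul(g, b))])
    if _is_scalar(a):
        return mul(b, a)
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data * b.data, [
        (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
    ])


def div(a, b) -> Tensor:
    if _is_scalar(b):
        return mul(a, 1.0 / b)
    if _is_scalar(a):
        b = _as_tensor(b)
        return _node(a / b.data, [(b, lambda g: neg(mul(g, div(a, mul(b, b)))))])
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data / b.data, [
        (a, lambda g: _unbroadcast(div(g, b), a.shape)),
        (b, lambda g: _unbroadcast(neg(mul(g, div(a, mul(b, b)))), b.shape)),
    ])


def pow_(a, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    return _node(a.data**p, [(a, lambda g: mul(g, mul(p, pow_(a, p - 1.0))))])


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)
    out = _node(out_data, [(a, lambda g: mul(g, out))])
    return out


def log(a) -> Tensor:
    a = _as_tensor(a)
    return _node(np.log(a.data), [(a, lambda g: div(g, a))])


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out = _node(np.tanh(a.data), [(a, lambda g: mul(g, sub(1.0, mul(out, out))))])
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = (a.data > 0).astype(a.data.dtype)
    return _node(a.data * mask, [(a, lambda g: mul(g, Tensor(mask)))])


def stop_gradient(a) -> Tensor:
    return Tensor(_as_tensor(a).data)


# -- linear algebra and shape ---------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp_a(g):
        return _unbroadcast(matmul(g, swapaxes(b, -1, -2)), a.shape)

    def vjp_b(g):
        return _unbroadcast(matmul(swapaxes(a, -1, -2), g), b.shape)

    return _node(np.matmul(a.data, b.data), [(a, vjp_a), (b, vjp_b)])


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    return _node(a.data.reshape(shape), [(a, lambda g: reshape(g, old))])


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _as_tensor(a)
    return _node(np.swapaxes(a.data, ax1, ax2), [(a, lambda g: swapaxes(g, ax1, ax2))])


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = tuple(np.argsort(axes))
    return _node(np.transpose(a.data, axes), [(a, lambda g: transpose(g, inv))])


def broadcast_to(a, shape) -> Tensor:
    a = _as_tensor(a)
    return _node(
        np.broadcast_to(a.data, shape).copy(), [(a, lambda g: _unbroadcast(g, a.shape))]
    )


def gsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    in_shape = a.shape

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(in_shape)), in_shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        axes = tuple(ax % len(in_shape) for ax in axes)
        if not keepdims:
            kd_shape = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
            g = reshape(g, kd_shape)
        return broadcast_to(g, in_shape)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), [(a, vjp)])


def gmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(gsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def gmax(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Max over one axis; ties share the incoming gradient equally."""
    a = _as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data).astype(a.data.dtype)
    mask /= mask.sum(axis=axis, keepdims=True)
    ax = axis % a.ndim

    def vjp(g):
        if not keepdims:
            kd_shape = tuple(1 if i == ax else s for i, s in enumerate(a.shape))
            g = reshape(g, kd_shape)
        return mul(broadcast_to(g, a.shape), Tensor(mask))

    return _node(out_data if keepdims else out_data.squeeze(axis), [(a, vjp)])


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    in_shape = a.shape
    return _node(a.data[idx], [(a, lambda g: _scatter(g, idx, in_shape))])


def _scatter(g, idx, shape) -> Tensor:
    g = _as_tensor(g)
    buf = np.zeros(shape, dtype=g.dtype)
    np.add.at(buf, idx, g.data)
    return _node(buf, [(g, lambda gg: getitem(gg, idx))])


def pad2d(a, pad: int) -> Tensor:
    """Zero-pad the two trailing (spatial) axes of a (B, C, H, W) tensor."""
    a = _as_tensor(a)
    if pad == 0:
        return a
    widths = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    sl = tuple([slice(None)] * (a.ndim - 2) + [slice(pad, -pad), slice(pad, -pad)])
    return _node(np.pad(a.data, widths), [(a, lambda g: getitem(g, sl))])


# -- im2col / col2im (the convolution backbone) ---------------------------

def _window_view(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]  # (B, C, Ho, Wo, kh, kw)


def im2col(a, kh: int, kw: int, sh: int = 1, sw: int = 1) -> Tensor:
    """Extract conv patches: (B, C, H, W) -> (B, Ho, Wo, C*kh*kw)."""
    a = _as_tensor(a)
    v = _window_view(a.data, kh, kw, sh, sw)
    b, c, ho, wo = v.shape[:4]
    out = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho, wo, c * kh * kw)
    in_shape = a.shape
    return _node(out, [(a, lambda g: col2im(g, in_shape, kh, kw, sh, sw))])


def col2im(g, x_shape, kh: int, kw: int, sh: int = 1, sw: int = 1) -> Tensor:
    """Adjoint of :func:`im2col`: scatter-add patches back to the image."""
    g = _as_tensor(g)
    b, ho, wo, _ = g.shape
    c = x_shape[1]
    gv = g.data.reshape(b, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    buf = np.zeros(x_shape, dtype=g.dtype)
    for i in range(kh):
        for j in range(kw):
            buf[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += gv[:, :, :, :, i, j]
    return _node(buf, [(g, lambda gg: im2col(gg, kh, kw, sh, sw))])


# -- composite neural-net operations --------------------------------------

def linear(x, w, b=None) -> Tensor:
    """x @ w (+ b) with x (..., in) and w (in, out)."""
    out = matmul(x, w)
    return out if b is None else add(out, b)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), x (B,C,H,W), w (O,C,kh,kw)."""
    o, c, kh, kw = w.shape
    cols = im2col(pad2d(x, padding), kh, kw, stride, stride)  # (B,Ho,Wo,C*kh*kw)
    wmat = swapaxes(reshape(w, (o, c * kh * kw)), 0, 1)  # (C*kh*kw, O)
    out = matmul(cols, wmat)  # (B, Ho, Wo, O)
    out = transpose(out, (0, 3, 1, 2))
    if b is not None:
        out = add(out, reshape(b, (1, o, 1, 1)))
    return out


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling with stride 2 on (B, C, H, W); H and W must be even."""
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    x = reshape(x, (b, c, h // 2, 2, w // 2, 2))
    x = transpose(x, (0, 1, 2, 4, 3, 5))
    x = reshape(x, (b, c, h // 2, w // 2, 4))
    return gmax(x, axis=-1)


def batchnorm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (batch, spatial) axes of (B, C, H, W).

    Always uses current-batch statistics (the transductive convention used
    in episodic meta-learning; no running averages are kept).
    """
    axes = (0, 2, 3)
    m = gmean(x, axis=axes, keepdims=True)
    xc = sub(x, m)
    v = gmean(mul(xc, xc), axis=axes, keepdims=True)
    xn = div(xc, sqrt(add(v, eps)))
    c = x.shape[1]
    return add(mul(xn, reshape(gamma, (1, c, 1, 1))), reshape(beta, (1, c, 1, 1)))


def layernorm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the trailing feature axis."""
    m = gmean(x, axis=-1, keepdims=True)
    xc = sub(x, m)
    v = gmean(mul(xc, xc), axis=-1, keepdims=True)
    return add(mul(div(xc, sqrt(add(v, eps))), gamma), beta)


def softmax(x, axis: int = -1) -> Tensor:
    z = sub(x, stop_gradient(gmax(x, axis=axis, keepdims=True)))
    e = exp(z)
    return div(e, gsum(e, axis=axis, keepdims=True))


def log_softmax(x, axis: int = -1) -> Tensor:
    z = sub(x, stop_gradient(gmax(x, axis=axis, keepdims=True)))
    return sub(z, log(gsum(exp(z), axis=axis, keepdims=True)))


def cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under ``logits`` (B, n_classes)."""
    labels = np.asarray(labels)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    return neg(gmean(gsum(mul(log_softmax(logits), Tensor(onehot)), axis=1)))


def dropout(x, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or rate is 0."""
    if not train or rate == 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return mul(x, Tensor(mask))


# -- reverse-mode driver ---------------------------------------------------

def _topo(output: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if parent.requires_grad and id(parent) not in seen:
                stack.append((parent, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own tape,
    so they can be differentiated again (second-order meta-gradients).
    Inputs unreachable from the output get zero gradients.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
        for node in reversed(_topo(output)):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if any(id(node) == id(inp) for inp in inputs):
                grads[id(node)] = g  # keep: this is a requested leaf
            for parent, vjp in node.parents:
                contribution = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = contribution if prev is None else add(prev, contribution)
        out = []
        for inp in inputs:
            g = grads.get(id(inp))
            if g is None:
                g = Tensor(np.zeros_like(inp.data))
            out.append(g if create_graph else g.detach())
    return out
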