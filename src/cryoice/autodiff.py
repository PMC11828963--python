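"""Reverse-mode automatic differentiation with higher-order support.

Optimization-based meta-learning needs gradients *through* gradient steps:
the meta-gradient of a query loss with respect to the shared initialization
differentiates the inner adaptation itself, which requires second-order
(gradient-of-gradient) machinery. This module provides a small, numpy-backed
tape: every primitive's vector-Jacobian product is itself expressed in these
primitives, so calling :func:`grad` with ``create_graph=True`` yields gradient
tensors that are again differentiable, to any order.

Only the operations the segmentation stack needs are implemented (elementwise
arithmetic, matmul, 2-D convolution, nearest upsampling/sum-pooling, reductions,
shape surgery). Convolution gradients are phrased as convolutions of dilated /
padded tensors, so double backward through conv layers works without special
cases.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "no_grad",
    "add", "sub", "mul", "neg", "power", "matmul",
    "relu", "sigmoid", "softplus", "log", "exp",
    "tsum", "tmean", "broadcast_to",
    "reshape", "transpose", "concat", "getitem", "pad", "flip", "dilate",
    "conv2d", "upsample_nearest2x", "sumpool2x",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape bookkeeping needed for reverse mode."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _vjp: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # -- introspection -----------------------------------------------------
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
        return Tensor(self.data, requires_grad=False)

    def copy(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=self.requires_grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

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


def _make(data, parents, vjp) -> Tensor:
    """Create an op output; record the tape edge only when tracking is on."""
    track = _GRAD_ENABLED and any(
        p.requires_grad or p._vjp is not None for p in parents
    )
    if track:
        return Tensor(data, requires_grad=True, _parents=tuple(parents), _vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum g down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = tsum(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    a = _wrap(a)
    in_shape = a.shape
    out = np.broadcast_to(a.data, shape)
    return _make(out.copy(), (a,), lambda g: (_unbroadcast(g, in_shape),))


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    return _make(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a, b):
    a, b = _wrap(a), _wrap(b)
    return _make(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape),
                            _unbroadcast(neg(g), b.shape)))


def neg(a):
    a = _wrap(a)
    return _make(-a.data, (a,), lambda g: (neg(g),))


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    return _make(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape),
                            _unbroadcast(mul(g, a), b.shape)))


def power(a, p: float):
    """a**p for a constant scalar exponent."""
    a = _wrap(a)
    p = float(p)
    return _make(a.data ** p, (a,),
                 lambda g: (mul(g, mul(Tensor(p), power(a, p - 1.0))),))


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    return _make(a.data @ b.data, (a, b),
                 lambda g: (matmul(g, transpose(b)),
                            matmul(transpose(a), g)))


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(a):
    a = _wrap(a)
    mask = (a.data > 0).astype(np.float64)
    return _make(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def sigmoid(a):
    a = _wrap(a)
    out_data = np.where(a.data >= 0,
                        1.0 / (1.0 + np.exp(-np.abs(a.data))),
                        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    out = _make(out_data, (a,), None)
    # derivative uses the output node itself so double backward sees σ(x)
    out._vjp = lambda g: (mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def softplus(a):
    """log(1 + exp(a)), overflow-safe; d/da = sigmoid(a)."""
    a = _wrap(a)
    out = np.maximum(a.data, 0.0) + np.log1p(np.exp(-np.abs(a.data)))
    return _make(out, (a,), lambda g: (mul(g, sigmoid(a)),))


def log(a):
    a = _wrap(a)
    return _make(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),))


def exp(a):
    a = _wrap(a)
    out = _make(np.exp(a.data), (a,), None)
    out._vjp = lambda g: (mul(g, out),)
    return out


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _wrap(a)
    in_shape = a.shape
    if axis is not None and not isinstance(axis, tuple):
        axis = (axis,)

    def vjp(g):
        if axis is not None and not keepdims:
            kshape = list(in_shape)
            for ax in axis:
                kshape[ax % len(in_shape)] = 1
            g = reshape(g, tuple(kshape))
        return (broadcast_to(g, in_shape),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = _wrap(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


# ---------------------------------------------------------------------------
# shape surgery
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = _wrap(a)
    in_shape = a.shape
    return _make(a.data.reshape(shape), (a,),
                 lambda g: (reshape(g, in_shape),))


def transpose(a, axes=None):
    a = _wrap(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,),
                 lambda g: (transpose(g, inv),))


def concat(parts: Sequence[Tensor], axis: int = 0):
    parts = [_wrap(p) for p in parts]
    sizes = [p.shape[axis] for p in parts]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        outs = []
        for i in range(len(parts)):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(getitem(g, tuple(idx)))
        return tuple(outs)

    return _make(np.concatenate([p.data for p in parts], axis=axis),
                 tuple(parts), vjp)


def getitem(a, idx):
    a = _wrap(a)
    in_shape = a.shape
    return _make(a.data[idx], (a,), lambda g: (_scatter(g, in_shape, idx),))


def _scatter(g: Tensor, shape: tuple, idx) -> Tensor:
    """Place g into zeros of `shape` at `idx` (adjoint of getitem)."""
    g = _wrap(g)

    def vjp(gg):
        return (getitem(gg, idx),)

    out = np.zeros(shape, dtype=np.float64)
    out[idx] = g.data
    return _make(out, (g,), vjp)


def pad(a, widths):
    """Zero-pad; widths is a ((before, after), ...) per-axis tuple."""
    a = _wrap(a)
    widths = tuple((int(b), int(e)) for b, e in widths)

    def vjp(g):
        idx = tuple(slice(b, g.shape[i] - e if e else None)
                    for i, (b, e) in enumerate(widths))
        return (getitem(g, idx),)

    return _make(np.pad(a.data, widths), (a,), vjp)


def flip(a, axes):
    a = _wrap(a)
    axes = tuple(axes)
    return _make(np.flip(a.data, axis=axes), (a,),
                 lambda g: (flip(g, axes),))


def dilate(a, stride: int, axes=(-2, -1)):
    """Insert stride-1 zeros between entries along `axes` (adjoint: strided slice)."""
    a = _wrap(a)
    if stride == 1:
        return a
    axes = tuple(ax % a.ndim for ax in axes)
    out_shape = list(a.shape)
    idx = [slice(None)] * a.ndim
    for ax in axes:
        out_shape[ax] = (a.shape[ax] - 1) * stride + 1
        idx[ax] = slice(None, None, stride)
    idx = tuple(idx)

    def vjp(g):
        return (getitem(g, idx),)

    out = np.zeros(out_shape, dtype=np.float64)
    out[idx] = a.data
    return _make(out, (a,), vjp)


# ---------------------------------------------------------------------------
# convolution and resampling
# ---------------------------------------------------------------------------

def _conv2d_raw(x: np.ndarray, w: np.ndarray, stride: int, padding: int) -> np.ndarray:
    """Cross-correlation, NCHW x OIHW -> NOHW, via im2col + tensordot."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {ci}")
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    # loop over whichever of (kernel positions, output positions) is smaller;
    # memory stays bounded by the output array either way
    if kh * kw <= ho * wo:
        acc = np.zeros((o, n, ho, wo))
        for u in range(kh):
            for v in range(kw):
                xs = x[:, :, u:u + (ho - 1) * stride + 1:stride,
                       v:v + (wo - 1) * stride + 1:stride]
                acc += np.tensordot(w[:, :, u, v], xs, axes=([1], [1]))
        return np.ascontiguousarray(acc.transpose(1, 0, 2, 3))
    out = np.empty((n, o, ho, wo))
    for u in range(ho):
        for v in range(wo):
            patch = x[:, :, u * stride:u * stride + kh,
                      v * stride:v * stride + kw]
            out[:, :, u, v] = np.tensordot(patch, w, axes=([1, 2, 3], [1, 2, 3]))
    return out


def conv2d(x, w, stride: int = 1, padding: int = 0):
    """2-D cross-correlation with differentiable (to any order) gradients.

    x: (N, C, H, W); w: (O, C, kH, kW). Both VJPs are themselves phrased as
    conv2d over dilated/padded operands, so meta-gradients through conv layers
    need no special handling.
    """
    x, w = _wrap(x), _wrap(w)
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    s, p = int(stride), int(padding)

    def vjp(g):
        # g: (N, O, Ho, Wo)
        gd = dilate(g, s)                       # (N, O, (Ho-1)s+1, ...)
        # grad wrt input: full correlation with the flipped kernel
        wf = transpose(flip(w, (2, 3)), (1, 0, 2, 3))   # (C, O, kh, kw)
        gx_full = conv2d(pad(gd, ((0, 0), (0, 0), (kh - 1, kh - 1),
                                  (kw - 1, kw - 1))), wf, stride=1, padding=0)
        # gx_full spans (Ho-1)s+kh which may undershoot h+2p; pad the tail
        eh = (h + 2 * p) - gx_full.shape[2]
        ew = (wd + 2 * p) - gx_full.shape[3]
        gx_full = pad(gx_full, ((0, 0), (0, 0), (0, eh), (0, ew)))
        gx = getitem(gx_full, (slice(None), slice(None),
                               slice(p, p + h), slice(p, p + wd)))
        # grad wrt kernel: correlate padded input with dilated g
        xp = pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        gw_full = conv2d(transpose(xp, (1, 0, 2, 3)),
                         transpose(gd, (1, 0, 2, 3)), stride=1, padding=0)
        gw = transpose(getitem(gw_full, (slice(None), slice(None),
                                         slice(0, kh), slice(0, kw))),
                       (1, 0, 2, 3))
        return (gx, gw)

    return _make(_conv2d_raw(x.data, w.data, s, p), (x, w), vjp)


def upsample_nearest2x(a):
    """Nearest-neighbour 2x upsampling on the trailing two axes."""
    a = _wrap(a)
    out = np.repeat(np.repeat(a.data, 2, axis=-2), 2, axis=-1)
    return _make(out, (a,), lambda g: (sumpool2x(g),))


def sumpool2x(a):
    """Sum over non-overlapping 2x2 blocks (adjoint of nearest upsampling)."""
    a = _wrap(a)
    h, w = a.shape[-2], a.shape[-1]
    lead = a.shape[:-2]
    out = a.data.reshape(*lead, h // 2, 2, w // 2, 2).sum(axis=(-3, -1))
    return _make(out, (a,), lambda g: (upsample_nearest2x(g),))


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs: Sequence[Tensor],
         create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar `output` w.r.t. each tensor in `inputs`.

    With ``create_graph=True`` the returned gradients are themselves nodes on
    the tape, so they can be differentiated again (second-order and beyond).
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")

    # topological order over the subgraph reachable from `output`
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape))}

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None or node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None:
                    continue
                acc = grads.get(id(p))
                grads[id(p)] = pg if acc is None else add(acc, pg)
    out = []
    for inp in inputs:
        g = grads.get(id(inp))
        if g is None:
            g = Tensor(np.zeros(inp.shape))
        out.append(g if create_graph else g.detach())
    return out
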