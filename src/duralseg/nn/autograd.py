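"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine supports exactly the operations the hemorrhage network needs:
broadcast arithmetic, matmul, stride-1 "same" convolution, 2x2 transposed
convolution, 2x2 max pooling, channel-wise max/mean reductions, batch-norm
building blocks and the usual pointwise nonlinearities.  Gradients are
accumulated on a tape built during the forward pass and replayed in reverse
topological order.  Correctness is pinned down by finite-difference checks
in the test suite rather than by construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """An n-d array node in the autodiff graph.

    Parameters
    ----------
    data : array-like
        Values; stored as a NumPy array (dtype preserved).
    requires_grad : bool
        Whether gradients should flow into this node.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (typically scalar) node through the tape."""
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, mul_scalar(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul_scalar(self, -1.0))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, other)
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / other)
        return mul(self, pow_scalar(_wrap(other), -1.0))

    def __pow__(self, p):
        return pow_scalar(self, p)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs(*ts):
    return any(t.requires_grad for t in ts)


def _unbroadcast(g, shape):
    """Sum gradient `g` down to `shape` (reverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _node(data, parents, backward):
    req = _needs(*parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else (),
                  _backward=backward if req else None)


# -- arithmetic ---------------------------------------------------------

def add(a, b):
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a, b):
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul_scalar(a, s):
    s = float(s)

    def bwd(g):
        a._accum(g * s)

    return _node(a.data * s, (a,), bwd)


def add_scalar(a, s):
    s = float(s)

    def bwd(g):
        a._accum(g)

    return _node(a.data + s, (a,), bwd)


def pow_scalar(a, p):
    p = float(p)
    out_data = a.data ** p

    def bwd(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), bwd)


def matmul(a, b):
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return _node(out_data, (a, b), bwd)


# -- reductions ---------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape))

    return _node(out_data, (a,), bwd)


def tmean(a, axis=None, keepdims=False):
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul_scalar(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tmax(a, axis, keepdims=False):
    """Max reduction over a single axis; ties send gradient to the first max."""
    out_data = a.data.max(axis=axis, keepdims=True)
    idx = np.expand_dims(a.data.argmax(axis=axis), axis)

    def bwd(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx, gg, axis)
        a._accum(ga)

    data = out_data if keepdims else np.squeeze(out_data, axis)
    return _node(data, (a,), bwd)


# -- pointwise nonlinearities ------------------------------------------

def relu(a):
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0)

    def bwd(g):
        a._accum(g * mask)

    return _node(out_data, (a,), bwd)


def leaky_relu(a, slope=0.001):
    mask = a.data >= 0
    out_data = np.where(mask, a.data, slope * a.data)

    def bwd(g):
        a._accum(g * np.where(mask, 1.0, slope))

    return _node(out_data, (a,), bwd)


def sigmoid(a):
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bwd)


def tlog(a):
    out_data = np.log(a.data)

    def bwd(g):
        a._accum(g / a.data)

    return _node(out_data, (a,), bwd)


def texp(a):
    out_data = np.exp(a.data)

    def bwd(g):
        a._accum(g * out_data)

    return _node(out_data, (a,), bwd)


def tsqrt(a):
    return pow_scalar(a, 0.5)


def clip_min(a, lo):
    """Lower clamp; gradient passes only where the input is above `lo`."""
    mask = a.data > lo
    out_data = np.where(mask, a.data, lo)

    def bwd(g):
        a._accum(g * mask)

    return _node(out_data, (a,), bwd)


# -- shape ops ----------------------------------------------------------

def reshape(a, shape):
    old = a.data.shape

    def bwd(g):
        a._accum(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), bwd)


def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _node(out_data, tuple(tensors), bwd)


# -- convolution / pooling ---------------------------------------------

def _conv2d_raw(x, w, pad):
    """Stride-1 cross-correlation with symmetric zero padding.

    x: (B, C, H, W), w: (O, C, kh, kw) -> (B, O, H', W') with H' = H when
    pad = (kh-1)//2 and kh odd.
    """
    kh, kw = w.shape[2], w.shape[3]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # B,C,Ho,Wo,kh,kw
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * kh * kw)
    out = cols @ w.reshape(w.shape[0], -1).T
    return out.reshape(b, ho, wo, w.shape[0]).transpose(0, 3, 1, 2), cols


def conv2d(x, w, bias=None, pad=None):
    """Same-padded stride-1 2-D convolution (cross-correlation convention)."""
    kh, kw = w.data.shape[2], w.data.shape[3]
    if pad is None:
        pad = (kh - 1) // 2
    out_data, cols = _conv2d_raw(x.data, w.data, pad)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    b, o, ho, wo = out_data.shape
    c = x.data.shape[1]

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, o)
        if w.requires_grad:
            gw = gmat.T @ cols
            w._accum(gw.reshape(w.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # grad wrt input = conv of g with channel-swapped, spatially
            # flipped kernel, padded so output matches the input size
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx, _ = _conv2d_raw(g, wf, pad=kh - 1 - pad)
            x._accum(gx)

    parents = (x, w) if bias is None else (x, w, bias)
    return _node(out_data, parents, bwd)


def conv_transpose2x2(x, w, bias=None):
    """2x2 stride-2 transposed convolution (exact spatial doubling).

    x: (B, C, H, W), w: (C, O, 2, 2) -> (B, O, 2H, 2W).  Windows do not
    overlap, so both passes are pure einsums.
    """
    out_data = np.einsum("bchw,coij->bohiwj", x.data, w.data)
    b, o, h, _, wd, _ = out_data.shape
    out_data = out_data.reshape(b, o, 2 * h, 2 * wd)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def bwd(g):
        gb = g.reshape(b, o, h, 2, wd, 2)
        if w.requires_grad:
            w._accum(np.einsum("bchw,bohiwj->coij", x.data, gb))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.einsum("bohiwj,coij->bchw", gb, w.data))

    parents = (x, w) if bias is None else (x, w, bias)
    return _node(out_data, parents, bwd)


def maxpool2x2(x):
    """2x2 stride-2 max pooling; ties route gradient to the first max."""
    b, c, h, w = x.data.shape
    win = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(b, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gwin = np.zeros((b, c, h // 2, w // 2, 4), dtype=x.data.dtype)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gx.reshape(b, c, h, w))

    return _node(out_data, (x,), bwd)
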