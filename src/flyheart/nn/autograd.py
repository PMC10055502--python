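"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the package's two network architectures
need (dense and 2-D convolutional layers, 2x2 max pooling, nearest-neighbour
upsampling, channel concatenation, elementwise nonlinearities, reductions).
Gradients are accumulated by walking the expression graph in reverse
topological order.  Everything is plain numpy; float32 is used for layer
parameters, but tensors preserve the dtype they are built from so gradient
checks can run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "neg", "div", "matmul", "relu", "sigmoid",
    "log", "clip", "tensor_sum", "tensor_mean", "reshape", "concat",
    "conv2d", "maxpool2", "upsample2", "pad2d", "crop2d",
]


def _as_array(x):
    a = np.asarray(x)
    if a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph ------------------------------------------------------------
    def _needs_grad(self):
        return self.requires_grad or bool(self._parents)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
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

    def __neg__(self):
        return neg(self)

    def __truediv__(self, scalar):
        return mul(self, 1.0 / float(scalar))

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g):
    if not t._needs_grad():
        return
    if t.grad is None:
        t.grad = g
    else:
        t.grad = t.grad + g


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise ----------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    out._backward = backward
    return out


def neg(a):
    a = _wrap(a)
    out = Tensor(-a.data, parents=(a,))
    out._backward = lambda g: _accum(a, -g)
    return out


def sub(a, b):
    return add(a, neg(_wrap(b)))


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    out._backward = backward
    return out


def relu(a):
    a = _wrap(a)
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def sigmoid(a):
    a = _wrap(a)
    x = a.data
    s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60))),
                 np.exp(np.clip(x, -60, 60)) / (1.0 + np.exp(np.clip(x, -60, 60))))
    s = s.astype(x.dtype)
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: _accum(a, g * s * (1.0 - s))
    return out


def log(a):
    a = _wrap(a)
    out = Tensor(np.log(a.data), parents=(a,))
    out._backward = lambda g: _accum(a, g / a.data)
    return out


def clip(a, lo, hi):
    a = _wrap(a)
    out = Tensor(np.clip(a.data, lo, hi), parents=(a,))
    inside = (a.data > lo) & (a.data < hi)
    out._backward = lambda g: _accum(a, g * inside)
    return out


# -- reductions and shaping ------------------------------------------------

def tensor_sum(a):
    a = _wrap(a)
    out = Tensor(np.asarray(a.data.sum()), parents=(a,))
    out._backward = lambda g: _accum(a, np.broadcast_to(g, a.shape).astype(a.data.dtype))
    return out


def tensor_mean(a):
    a = _wrap(a)
    n = a.data.size
    return mul(tensor_sum(a), 1.0 / n)


def reshape(a, shape):
    a = _wrap(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: _accum(a, g.reshape(a.shape))
    return out


def concat(tensors, axis=1):
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = backward
    return out


# -- dense ----------------------------------------------------------------

def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = backward
    return out


# -- convolution ----------------------------------------------------------
# Image tensors use channels-last (N, H, W, C) layout throughout: every
# im2col slice copy is then contiguous along the channel axis, which keeps
# the convolution close to a single large matmul.

def conv2d(x, w, b=None):
    """Same-padded stride-1 2-D convolution (cross-correlation).

    x: (N, H, W, C); w: (F, C, kh, kw) with odd kernel dims; b: (F,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    f, c, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    n, h, wid, _ = x.shape
    cols = np.empty((n, h, wid, kh * kw * c), dtype=xp.dtype)
    k = 0
    for i in range(kh):
        for j in range(kw):
            cols[..., k * c:(k + 1) * c] = xp[:, i:i + h, j:j + wid, :]
            k += 1
    wmat = w.data.transpose(2, 3, 1, 0).reshape(kh * kw * c, f)
    y = cols.reshape(-1, kh * kw * c) @ wmat
    y = y.reshape(n, h, wid, f)
    parents = [x, w]
    if b is not None:
        b = _wrap(b)
        y = y + b.data
        parents.append(b)
    out = Tensor(y, parents=tuple(parents))

    def backward(g):
        gf = g.reshape(-1, f)
        if w._needs_grad():
            gw = cols.reshape(-1, kh * kw * c).T @ gf          # (kh*kw*C, F)
            gw = gw.reshape(kh, kw, c, f).transpose(3, 2, 0, 1)
            _accum(w, gw.astype(w.data.dtype))
        if b is not None and b._needs_grad():
            _accum(b, gf.sum(axis=0).astype(b.data.dtype))
        if x._needs_grad():
            gcols = (gf @ wmat.T).reshape(n, h, wid, kh * kw * c)
            gxp = np.zeros_like(xp)
            k = 0
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + h, j:j + wid, :] += gcols[..., k * c:(k + 1) * c]
                    k += 1
            gx = gxp[:, ph:ph + h, pw:pw + wid, :] if (ph or pw) else gxp
            _accum(x, gx.astype(x.data.dtype))

    out._backward = backward
    return out


# -- pooling / resampling --------------------------------------------------

def maxpool2(x):
    """2x2 max pooling, stride 2, on (N, H, W, C).  Spatial dims must be even."""
    x = _wrap(x)
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    win = win.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    out = Tensor(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def backward(g):
        gw = np.zeros_like(win)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        _accum(x, gw.reshape(n, h, w, c))

    out._backward = backward
    return out


def upsample2(x):
    """Nearest-neighbour 2x upsampling on (N, H, W, C)."""
    x = _wrap(x)
    out = Tensor(x.data.repeat(2, axis=1).repeat(2, axis=2), parents=(x,))

    def backward(g):
        n, h2, w2, c = g.shape
        _accum(x, g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)))

    out._backward = backward
    return out


def pad2d(x, ph, pw):
    """Zero-pad the bottom/right of the spatial dims of (N, H, W, C)."""
    x = _wrap(x)
    out = Tensor(np.pad(x.data, ((0, 0), (0, ph), (0, pw), (0, 0))), parents=(x,))
    n, h, w, c = x.shape
    out._backward = lambda g: _accum(x, g[:, :h, :w, :])
    return out


def crop2d(x, h, w):
    """Crop the spatial dims of (N, H, W, C) from the top-left corner."""
    x = _wrap(x)
    out = Tensor(x.data[:, :h, :w, :], parents=(x,))

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, :h, :w, :] = g
        _accum(x, gx)

    out._backward = backward
    return out
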