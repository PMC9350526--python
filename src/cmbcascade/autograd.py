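"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the segmentation networks need:
broadcasting arithmetic, matmul, elementwise nonlinearities, reductions,
2-D convolution with stride/dilation (im2col), 2×2 max pooling, bilinear
×2 upsampling, channel concatenation and value clipping.

Gradients are accumulated by a topological backward sweep.  Correctness is
established against central finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "concatenate", "conv2d", "maxpool2x2", "upsample_bilinear2x",
           "batchnorm2d", "no_grad"]

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class _BufferPool:
    """Recycle large scratch arrays (im2col columns, padded inputs)."""

    def __init__(self):
        self._free: dict = {}

    def take(self, shape, dtype) -> np.ndarray:
        key = (shape, np.dtype(dtype).str)
        bucket = self._free.get(key)
        if bucket:
            return bucket.pop()
        return np.empty(shape, dtype=dtype)

    def give(self, arr: np.ndarray) -> None:
        key = (arr.shape, arr.dtype.str)
        self._free.setdefault(key, []).append(arr)


_pool = _BufferPool()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=_grad_enabled
                     and any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data**p
        x = self.data

        def backward(g):
            return (g * p * x ** (p - 1.0),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        # numerically stable logistic
        s = np.where(self.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(self.data))),
                     np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))

        def backward(g):
            return (g * s * (1.0 - s),)

        return self._make(s, (self,), backward)

    def log(self):
        x = self.data

        def backward(g):
            return (g / x,)

        return self._make(np.log(x), (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            return (g * e,)

        return self._make(e, (self,), backward)

    def sqrt(self):
        return self**0.5

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through the interior."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            return (g * mask,)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            return (g.reshape(old),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- backward sweep --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        return float(self.data)


# -- structural ops ------------------------------------------------------------

def concatenate(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data, requires_grad=_grad_enabled
                 and any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dilation: int):
    """Column matrix (N, C*kh*kw, oh*ow) assembled by kernel-tap block copies."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    oh = (x.shape[2] - eh) // stride + 1
    ow = (x.shape[3] - ew) // stride + 1
    cols = _pool.take((n, c, kh, kw, oh, ow), x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i * dilation:i * dilation + stride * oh:stride,
                                 j * dilation:j * dilation + stride * ow:stride]
    return cols, oh, ow, x.shape


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding/dilation.

    w has shape (C_out, C_in, kh, kw); b has shape (C_out,).
    """
    x = Tensor._wrap(x)
    w = Tensor._wrap(w)
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    cols6d, oh, ow, padded_shape = _im2col(x.data, kh, kw, stride, padding, dilation)
    cols = cols6d.reshape(n, cin * kh * kw, oh * ow)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(n, cout, oh, ow)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1)
    build_graph = _grad_enabled and (x.requires_grad or w.requires_grad
                                     or (b is not None and b.requires_grad))
    if not build_graph:
        _pool.give(cols6d)
        return Tensor(out_data)

    def backward(g):
        gmat = g.reshape(n, cout, oh * ow)
        gw = np.tensordot(gmat, cols, axes=([0, 2], [0, 2])).reshape(cout, cin, kh, kw)
        gcols = np.matmul(wmat.T, gmat).reshape(n, cin, kh, kw, oh, ow)
        # col2im scatter-add into the padded input
        gx_pad = np.zeros(padded_shape, dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                gx_pad[:, :, i * dilation:i * dilation + stride * oh:stride,
                       j * dilation:j * dilation + stride * ow:stride] += gcols[:, :, i, j]
        if padding:
            gx = gx_pad[:, :, padding:padding + h, padding:padding + wd]
        else:
            gx = gx_pad
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        _pool.give(cols6d)  # the closure fires once per graph
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, requires_grad=True)
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    x = Tensor._wrap(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(n, c, h, w),)

    out = Tensor(out_data, requires_grad=_grad_enabled and x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = backward
    return out


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix, half-pixel-center convention."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    a[np.arange(n_out), i0] += 1.0 - frac
    a[np.arange(n_out), i1] += frac
    return a


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Double both spatial dimensions by bilinear interpolation (a linear map)."""
    x = Tensor._wrap(x)
    n, c, h, w = x.data.shape
    ar = _interp_matrix(2 * h, h, x.data.dtype)
    ac = _interp_matrix(2 * w, w, x.data.dtype)
    out_data = np.einsum("oh,nchw,pw->ncop", ar, x.data, ac, optimize=True)

    def backward(g):
        return (np.einsum("oh,ncop,pw->nchw", ar, g, ac, optimize=True),)

    out = Tensor(out_data, requires_grad=_grad_enabled and x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = backward
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused batch normalization over (N, H, W) per channel.

    Returns (out, batch_mean, batch_var) with the statistics as plain arrays
    (for the caller's running-average bookkeeping).  The backward pass uses
    the closed-form batch-norm gradient.
    """
    x = Tensor._wrap(x)
    n, c, h, w = x.data.shape
    m = n * h * w
    mu = x.data.mean(axis=(0, 2, 3))
    xc = x.data - mu.reshape(1, c, 1, 1)
    var = np.mean(xc * xc, axis=(0, 2, 3))
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = xc * ivar.reshape(1, c, 1, 1)
    out_data = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        ggamma = np.sum(g * xhat, axis=(0, 2, 3))
        gbeta = np.sum(g, axis=(0, 2, 3))
        coef = (gamma.data * ivar / m).reshape(1, c, 1, 1)
        gx = coef * (m * g - gbeta.reshape(1, c, 1, 1)
                     - xhat * ggamma.reshape(1, c, 1, 1))
        return (gx, ggamma, gbeta)

    parents = (x, gamma, beta)
    out = Tensor(out_data, requires_grad=_grad_enabled
                 and any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out, mu, var
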