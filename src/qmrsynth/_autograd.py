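"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the synthesis network needs: 2-D "same"
convolution (im2col), 2x2 max pooling and nearest-neighbour upsampling,
channel concatenation, ReLU / sigmoid, element-wise arithmetic including
exp, abs, reciprocal and element-wise maximum (the latent fusion), and
masked reductions for the MAE loss.  Layout is NCHW throughout.

Gradients are checked against central finite differences in the test
suite; everything is deterministic given a seeded NumPy RNG.
"""

from __future__ import annotations

import ctypes

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:
    # Large temporaries (im2col buffers) would otherwise each be a fresh
    # mmap; keeping them on the heap lets glibc reuse the blocks.
    _libc = ctypes.CDLL("libc.so.6")
    _libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
    _libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
except OSError:  # pragma: no cover - non-glibc platform
    pass

__all__ = ["Tensor", "conv2d", "maxpool2", "upsample2", "concat", "relu",
           "sigmoid", "maximum", "exp", "absolute", "reciprocal", "masked_mae",
           "Adam", "set_dtype"]

# float32 keeps training fast; tests may switch to float64 for finite-
# difference gradient checks
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = dtype


class Tensor:
    """An array node in the backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
        # drop closures so the graph frees by reference counting alone
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        return _binop(self, other, lambda a, b: a + b,
                      lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, lambda a, b: a - b,
                      lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _binop(self, other, lambda a, b: b - a,
                      lambda g, a, b: -g, lambda g, a, b: g)

    def __mul__(self, other):
        return _binop(self, other, lambda a, b: a * b,
                      lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def sum(self):
        out = Tensor(self.data.sum())
        out._parents = (self,)

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient g down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _binop(a, b, fwd, bwa, bwb) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(fwd(a.data, b.data))
    out._parents = (a, b)

    def bw(g):
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(bwa(g, a.data, b.data), a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(bwb(g, a.data, b.data), b.data.shape))
    out._backward = bw
    return out


def _unop(x, fwd, bwd) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(fwd(x.data))
    out._parents = (x,)
    out_data = out.data

    def bw(g):
        if x.requires_grad or x._parents:
            x._accum(bwd(g, x.data, out_data))
    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    return _unop(x, lambda a: np.maximum(a, 0.0),
                 lambda g, a, o: g * (a > 0))


def sigmoid(x: Tensor) -> Tensor:
    return _unop(x, lambda a: 1.0 / (1.0 + np.exp(-a)),
                 lambda g, a, o: g * o * (1.0 - o))


def exp(x: Tensor) -> Tensor:
    return _unop(x, np.exp, lambda g, a, o: g * o)


def absolute(x: Tensor) -> Tensor:
    return _unop(x, np.abs, lambda g, a, o: g * np.sign(a))


def reciprocal(x: Tensor) -> Tensor:
    return _unop(x, lambda a: 1.0 / a, lambda g, a, o: -g * o * o)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise max of two equal-shape tensors (ties route to ``a``)."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError("maximum requires equal shapes")
    take_a = a.data >= b.data
    return _binop(a, b, lambda x, y: np.maximum(x, y),
                  lambda g, x, y: g * take_a,
                  lambda g, x, y: g * ~take_a)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    ndim = out.data.ndim

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 "same" 2-D convolution (odd kernel), x (N,C,H,W), w (Co,C,kh,kw)."""
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    assert ci == c and kh % 2 == 1 and kw % 2 == 1

    if kh == kw == 1:  # 1x1: pure channel mixing, no im2col needed
        xm = x.data.reshape(n, c, h * wd)
        y = np.einsum("oc,ncp->nop", w.data[:, :, 0, 0], xm, optimize=True)
        out = Tensor(y.reshape(n, co, h, wd) + b.data[None, :, None, None])
        out._parents = (x, w, b)

        def bw1(g):
            gy = g.reshape(n, co, h * wd)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.einsum("nop,ncp->oc", gy, xm, optimize=True)
                w._accum(gw[:, :, None, None])
            if x.requires_grad or x._parents:
                gx = np.einsum("co,nop->ncp", w.data[:, :, 0, 0].T, gy, optimize=True)
                x._accum(gx.reshape(n, c, h, wd))
        out._backward = bw1
        return out

    cols = _im2col(x.data, kh, kw)
    wmat = w.data.reshape(co, -1)
    y = cols @ wmat.T + b.data
    out = Tensor(y.reshape(n, h, wd, co).transpose(0, 3, 1, 2))
    out._parents = (x, w, b)

    def bw(gy):
        if b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gym = gy.transpose(0, 2, 3, 1).reshape(n * h * wd, co)
            w._accum((gym.T @ cols).reshape(co, c, kh, kw))
        if x.requires_grad or x._parents:
            # gradient w.r.t. input = 'same' conv of gy with the spatially
            # flipped, channel-transposed kernels
            w_rot = np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            gcols = _im2col(gy, kh, kw)
            gx = gcols @ w_rot.reshape(c, -1).T
            x._accum(gx.reshape(n, h, wd, c).transpose(0, 3, 1, 2))
    out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling; spatial dims must be even."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = Tensor(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0])
    out._parents = (x,)

    def bw(g):
        if x.requires_grad or x._parents:
            gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gx.reshape(n, c, h, w))
    out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    n, c, h, w = x.data.shape
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3))
    out._parents = (x,)

    def bw(g):
        if x.requires_grad or x._parents:
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    out._backward = bw
    return out


def masked_mae(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean absolute error restricted to ``mask`` (the pixel domain chi)."""
    nvox = float(mask.sum())
    if nvox == 0:
        raise ValueError("empty loss domain")
    diff = absolute(pred - Tensor(target))
    return (diff * Tensor(mask.astype(float))).sum() * (1.0 / nvox)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
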