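"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the package's networks need: broadcasted
arithmetic, matmul, dilated 1-D and 2-D convolutions (stride 1, "same"
padding), pooling/upsampling, relu/softplus/exp/log and reductions.
float32 throughout.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "conv2d", "avg_pool2d", "upsample2d"]

DTYPE = np.float32


def _tune_allocator():
    """Raise glibc's mmap threshold so multi-MB activation buffers are reused
    from the heap instead of being mmap'ed and page-faulted on every op; this
    is worth an order of magnitude on the conv-heavy training loop."""
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 28)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 28)  # M_TRIM_THRESHOLD
    except Exception:  # non-glibc platforms: simply slower
        pass


_tune_allocator()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return np.asarray(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE)  # owning copy
        else:
            self.grad += g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * self.data / other.data**2, other.shape))
        out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))
        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))
        out._backward = bwd
        return out

    def softplus(self):
        """log(1 + exp(x)), numerically stable; derivative sigmoid(x)."""
        x = self.data
        val = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0)
        out = Tensor(val, self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                # stable sigmoid: never exponentiate a positive argument
                e = np.exp(-np.abs(x))
                sig = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
                self._accum(out.grad * sig)
        out._backward = bwd
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad * out.data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = bwd
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))
        out._backward = bwd
        return out

    # -- autograd ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward()
        # break closure reference cycles so big activation buffers free
        # promptly (single-shot backward; no higher-order gradients)
        for t in topo:
            t._backward = None
            t._prev = ()


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accum(g)
    out._backward = bwd
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Dilated 1-D convolution, stride 1, zero "same" padding.

    Channel-first layout for speed: x is (Cin, N, T) (channel, voxel batch,
    time), w is (Cout, Cin, K) with K odd, b is (Cout,).  Non-causal: the pad
    is symmetric, so the output at time t sees ``(K-1)*dilation/2`` frames on
    each side.  Returns (Cout, N, T).
    """
    Cin, N, T = x.shape
    Cout, _, K = w.shape
    pad = dilation * (K - 1) // 2
    xp = np.zeros((Cin, N, T + 2 * pad), dtype=DTYPE)
    xp[:, :, pad : pad + T] = x.data
    # im2col in channel-first layout: one BLAS gemm, no transposes
    cols = np.empty((Cin * K, N * T), dtype=DTYPE)
    for k in range(K):
        cols[k * Cin : (k + 1) * Cin] = xp[:, :, k * dilation : k * dilation + T].reshape(Cin, N * T)
    w2 = w.data.transpose(2, 1, 0).reshape(Cin * K, Cout)  # (Cin*K, Cout)
    out_data = w2.T @ cols  # (Cout, N*T)
    if b is not None:
        out_data += b.data[:, None]
    out_data = out_data.reshape(Cout, N, T)
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def bwd():
        g2 = out.grad.reshape(Cout, N * T)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=1))
        if w.requires_grad:
            gw = (cols @ g2.T).reshape(K, Cin, Cout).transpose(2, 1, 0)
            w._accum(gw)
        if x.requires_grad:
            gcols = w2 @ g2  # (Cin*K, N*T)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k * dilation : k * dilation + T] += gcols[
                    k * Cin : (k + 1) * Cin
                ].reshape(Cin, N, T)
            x._accum(gxp[:, :, pad : pad + T] if pad else gxp)
    out._backward = bwd
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2-D convolution, stride 1, zero "same" padding; kernel odd (1 or 3).

    x: (N, Cin, H, W), w: (Cout, Cin, K, K), b: (Cout,).
    """
    N, Cin, H, W = x.shape
    Cout, _, K, _ = w.shape
    pad = (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    out_data = np.zeros((N, Cout, H, W), dtype=DTYPE)
    for i in range(K):
        for j in range(K):
            seg = xp[:, :, i : i + H, j : j + W]
            out_data += np.einsum("nchw,oc->nohw", seg, w.data[:, :, i, j], optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def bwd():
        g = out.grad
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad or x.requires_grad:
            gxp = np.zeros_like(xp) if x.requires_grad else None
            if w.requires_grad and w.grad is None:
                w.grad = np.zeros_like(w.data)
            for i in range(K):
                for j in range(K):
                    seg = xp[:, :, i : i + H, j : j + W]
                    if w.requires_grad:
                        w.grad[:, :, i, j] += np.einsum(
                            "nohw,nchw->oc", g, seg, optimize=True
                        ).astype(DTYPE, copy=False)
                    if x.requires_grad:
                        gxp[:, :, i : i + H, j : j + W] += np.einsum(
                            "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                        )
            if x.requires_grad:
                x._accum(gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp)
    out._backward = bwd
    return out


def avg_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    N, C, H, W = x.shape
    f = factor
    if H % f or W % f:
        raise ValueError("spatial size must be divisible by the pooling factor")
    out_data = x.data.reshape(N, C, H // f, f, W // f, f).mean(axis=(3, 5))
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd():
        if x.requires_grad:
            g = out.grad[:, :, :, None, :, None] / (f * f)
            g = np.broadcast_to(g, (N, C, H // f, f, W // f, f)).reshape(N, C, H, W)
            x._accum(g)
    out._backward = bwd
    return out


def upsample2d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling."""
    N, C, H, W = x.shape
    f = factor
    out_data = np.repeat(np.repeat(x.data, f, axis=2), f, axis=3)
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd():
        if x.requires_grad:
            g = out.grad.reshape(N, C, H, f, W, f).sum(axis=(3, 5))
            x._accum(g)
    out._backward = bwd
    return out
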