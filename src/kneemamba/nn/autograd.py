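"""Reverse-mode automatic differentiation on NumPy arrays.

A small dynamic-tape engine: every operation builds a node holding its parents
and a closure that maps the output gradient to parent gradients.  It supports
exactly the operators the segmentation network needs (dense/convolutional
linear maps, pooling, normalisation statistics, element-wise nonlinearities,
reshaping, and a linear state-space scan with an analytic adjoint pass).

Arrays keep whatever float dtype they are given; the network uses float32,
the numerical tests float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "matmul", "ssm_scan_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- basic introspection ------------------------------------------------
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph mechanics ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        out._backward = lambda g: ((self, _unbroadcast(g, self.shape)),
                                   (other, _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: ((self, -g),)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return (-self) + self._lift(other)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        out._backward = lambda g: ((self, _unbroadcast(g * other.data, self.shape)),
                                   (other, _unbroadcast(g * self.data, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))
        out._backward = lambda g: ((self, g * exponent * self.data ** (exponent - 1.0)),)
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        out._backward = bwd
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: ((self, g.reshape(self.shape)),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: ((self, g.transpose(inv)),)
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis).copy(), self.requires_grad, (self,))
        out._backward = lambda g: ((self, np.flip(g, axis=axis).copy()),)
        return out

    # -- nonlinearities -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: ((self, g * mask),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: ((self, g * s * (1.0 - s)),)
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, self.requires_grad, (self,))
        out._backward = lambda g: ((self, g * (s + self.data * s * (1.0 - s))),)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: ((self, g * e),)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: ((self, g / self.data),)
        return out

    def sqrt(self):
        return self ** 0.5

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: (
            (self, s * (g - (g * s).sum(axis=axis, keepdims=True))),)
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, self.requires_grad, (self,))
        out._backward = lambda g: (
            (self, g - np.exp(ls) * g.sum(axis=axis, keepdims=True)),)
        return out


def normalize(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
              eps: float = 1e-5) -> Tensor:
    """Fused affine normalisation over `axes` (layer/batch norm core).

    y = (x - mean) / sqrt(var + eps) * gamma + beta, with gamma/beta already
    shaped to broadcast against x.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def bwd(g):
        dxhat = g * gamma.data
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) * inv
        dgamma = _unbroadcast(g * xhat, gamma.shape)
        dbeta = _unbroadcast(g, beta.shape)
        return ((x, dx), (gamma, dgamma), (beta, dbeta))

    out._backward = bwd
    return out


# -- multi-input operations ------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out = Tensor(np.matmul(a.data, b.data),
                 a.requires_grad or b.requires_grad, (a, b))

    def bwd(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        if a.ndim == 1:  # (k,) @ (..., k, n)
            ga = _unbroadcast(np.matmul(g[..., None, :], np.swapaxes(b.data, -1, -2))[..., 0, :], a.shape)
        else:
            ga = _unbroadcast(ga, a.shape)
        if b.ndim == 1:
            gb = _unbroadcast(np.matmul(a.data[..., None], g[..., None, :]).sum(-2), b.shape)
        else:
            gb = _unbroadcast(gb, b.shape)
        return ((a, ga), (b, gb))

    out._backward = bwd
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        pieces = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            pieces.append((t, g[tuple(sl)]))
        return tuple(pieces)

    out._backward = bwd
    return out


# -- convolution -----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int | tuple[int, int] = 0) -> Tensor:
    """2D cross-correlation, NCHW layout, weight (O, C, kh, kw)."""
    B, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {Cw}")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (B, C, OH, OW, kh, kw)
    y = np.einsum("bcijkl,ockl->boij", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, any(p.requires_grad for p in parents), parents)
    OH, OW = y.shape[2], y.shape[3]

    def bwd(g):
        gw = np.einsum("bcijkl,boij->ockl", win, g, optimize=True)
        gxp = np.zeros_like(xp)
        # scatter each kernel tap's contribution back onto the padded input
        for ki in range(kh):
            for kj in range(kw):
                contrib = np.einsum("boij,oc->bcij", g, w.data[:, :, ki, kj], optimize=True)
                gxp[:, :, ki:ki + OH * stride:stride, kj:kj + OW * stride:stride] += contrib
        gx = gxp[:, :, ph:ph + H, pw:pw + W]
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    out._backward = bwd
    return out


def _pool_bins(n_in: int, n_out: int):
    starts = (np.arange(n_out) * n_in) // n_out
    ends = -(-(np.arange(1, n_out + 1) * n_in) // n_out)  # ceil division
    return starts, ends


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Average pooling onto an (oh, ow) grid with torch-style bin edges."""
    B, C, H, W = x.shape
    oh, ow = out_hw
    rs, re = _pool_bins(H, oh)
    cs, ce = _pool_bins(W, ow)
    y = np.empty((B, C, oh, ow), dtype=x.dtype)
    for i in range(oh):
        for j in range(ow):
            y[:, :, i, j] = x.data[:, :, rs[i]:re[i], cs[j]:ce[j]].mean(axis=(2, 3))
    out = Tensor(y, x.requires_grad, (x,))

    def bwd(g):
        gx = np.zeros_like(x.data)
        for i in range(oh):
            for j in range(ow):
                area = (re[i] - rs[i]) * (ce[j] - cs[j])
                gx[:, :, rs[i]:re[i], cs[j]:ce[j]] += g[:, :, i, j, None, None] / area
        return ((x, gx),)

    out._backward = bwd
    return out


def upsample_nearest(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    B, C, H, W = x.shape
    OH, OW = out_hw
    ri = (np.arange(OH) * H) // OH
    ci = (np.arange(OW) * W) // OW
    out = Tensor(x.data[:, :, ri][:, :, :, ci], x.requires_grad, (x,))

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), ri[:, None], ci[None, :]), g)
        return ((x, gx),)

    out._backward = bwd
    return out


# -- linear state-space scan -----------------------------------------------

def ssm_scan_grouped(x: Tensor, A: Tensor, B: Tensor, C: Tensor, D: Tensor,
                     h0: np.ndarray | None = None) -> Tensor:
    """Grouped linear state-space scan.

    Runs h_t = A h_{t-1} + B x_t ; y_t = C h_t + D x_t independently for G
    parameter groups (e.g. the four 2D scan directions), vectorised over a
    batch axis.  Shapes: x (G, Bsz, T, Din); A (G, N, N); B (G, N, Din);
    C (G, Dout, N); D (G, Dout, Din) or (G, Din) as a diagonal feed-through
    (then Dout == Din).  The backward pass is the adjoint recurrence
    lambda_t = C^T g_t + A^T lambda_{t+1}.
    """
    xd = x.data
    G, Bsz, T, Din = xd.shape
    N = A.shape[-1]
    diag_D = D.data.ndim == 2
    At = np.swapaxes(A.data, -1, -2)
    Bt = np.swapaxes(B.data, -1, -2)
    h = (np.zeros((G, Bsz, N), dtype=xd.dtype) if h0 is None
         else np.broadcast_to(h0, (G, Bsz, N)).astype(xd.dtype).copy())
    hs = np.empty((G, Bsz, T, N), dtype=xd.dtype)
    for t in range(T):
        h = np.matmul(h, At) + np.matmul(xd[:, :, t], Bt)
        hs[:, :, t] = h
    y = np.matmul(hs, np.swapaxes(C.data, -1, -2)[:, None])
    if diag_D:
        y = y + xd * D.data[:, None, None, :]
    else:
        y = y + np.matmul(xd, np.swapaxes(D.data, -1, -2)[:, None])
    Dout = y.shape[-1]
    out = Tensor(y, any(p.requires_grad for p in (x, A, B, C, D)), (x, A, B, C, D))

    def bwd(g):
        lam = np.zeros((G, Bsz, N), dtype=xd.dtype)
        gx = np.empty_like(xd)
        gA = np.zeros_like(A.data)
        gB = np.zeros_like(B.data)
        h_init = (np.zeros((G, Bsz, N), dtype=xd.dtype) if h0 is None
                  else np.broadcast_to(h0, (G, Bsz, N)).astype(xd.dtype))
        for t in range(T - 1, -1, -1):
            lam = np.matmul(g[:, :, t], C.data) + np.matmul(lam, A.data)
            h_prev = hs[:, :, t - 1] if t > 0 else h_init
            gA += np.einsum("gbn,gbm->gnm", lam, h_prev, optimize=True)
            gB += np.einsum("gbn,gbi->gni", lam, xd[:, :, t], optimize=True)
            gx[:, :, t] = np.matmul(lam, B.data)
        gC = np.einsum("gbto,gbtn->gon", g, hs, optimize=True)
        if diag_D:
            gx += g * D.data[:, None, None, :]
            gD = np.einsum("gbto,gbto->go", g, xd, optimize=True)
        else:
            gx += np.matmul(g, D.data[:, None])
            gD = np.einsum("gbto,gbti->goi", g, xd, optimize=True)
        return ((x, gx), (A, gA), (B, gB), (C, gC), (D, gD))

    out._backward = bwd
    return out


def ssm_scan_op(x: Tensor, A: Tensor, B: Tensor, C: Tensor, D: Tensor,
                h0: np.ndarray | None = None) -> Tensor:
    """Single-system scan: x (..., T, Din) -> y (..., T, Dout).

    Thin wrapper over :func:`ssm_scan_grouped` with one group; leading axes
    of `x` are flattened into the batch.
    """
    xd = x.data
    T, Din = xd.shape[-2], xd.shape[-1]
    batch = xd.shape[:-2]
    bsz = int(np.prod(batch)) if batch else 1
    x4 = x.reshape(1, bsz, T, Din)
    A3 = A.reshape((1,) + A.shape)
    B3 = B.reshape((1,) + B.shape)
    C3 = C.reshape((1,) + C.shape)
    D3 = D.reshape((1,) + D.shape)
    y = ssm_scan_grouped(x4, A3, B3, C3, D3, h0=h0)
    Dout = y.shape[-1]
    return y.reshape(batch + (T, Dout))
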