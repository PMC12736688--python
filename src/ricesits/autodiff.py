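"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the tensor operations the time-series transformer needs,
with fused forward/backward kernels for the hot paths (affine maps, scaled
dot-product attention, layer normalisation, softmax cross-entropy) so that
training stays matmul-bound on a single CPU core.

Arrays are stored in ``DTYPE`` (float32 by default); gradient-check tests may
switch the module-level ``DTYPE`` to float64 for tighter numerical tolerance.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._prev: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray, fresh: bool = False) -> None:
        """Add ``g`` to the stored gradient. ``fresh=True`` promises that
        the caller owns ``g`` exclusively, allowing a copy-free store."""
        if self.grad is None:
            if fresh and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if node._prev:
                # tear down the graph as it is consumed: backward closures
                # capture their output tensor, so leaving them in place
                # creates reference cycles that pile up garbage across
                # training steps; intermediate grads are also spent by now
                node._backward = None
                node._prev = ()
                node.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __neg__(self):
        return mul(self, _as_tensor(np.asarray(-1.0, dtype=self.data.dtype)))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward_factory) -> Tensor:
    """Build an output tensor; attach a backward closure if grads are live."""
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward_factory(out)
    else:
        out.requires_grad = False
        out._prev = ()
        out._backward = None
    return out


# -- elementwise ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad, b.data.shape))
        return run
    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-out.grad, b.data.shape))
        return run
    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))
        return run
    return _make(a.data * b.data, (a, b), bw)


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)

    def bw(out):
        def run():
            a._accumulate(out.grad * e, fresh=True)
        return run
    return _make(e, (a,), bw)


def log(a: Tensor) -> Tensor:
    def bw(out):
        def run():
            a._accumulate(out.grad / a.data)
        return run
    return _make(np.log(a.data), (a,), bw)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def bw(out):
        def run():
            a._accumulate(out.grad * (1.0 - t * t), fresh=True)
        return run
    return _make(t, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    e = np.exp(-np.abs(a.data))  # stable: argument is always <= 0
    s = np.where(a.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

    def bw(out):
        def run():
            a._accumulate(out.grad * s * (1.0 - s), fresh=True)
        return run
    return _make(s, (a,), bw)


_GELU_C = 0.7978845608028654  # sqrt(2/pi)


def gelu(a: Tensor) -> Tensor:
    """GELU, tanh approximation (matches the common transformer kernel)."""
    x = a.data
    x2 = x * x
    t = x2 * x
    t *= 0.044715
    t += x
    t *= _GELU_C
    np.tanh(t, out=t)
    y = 1.0 + t
    y *= x
    y *= 0.5

    def bw(out):
        def run():
            # dy/dx = 0.5(1+t) + 0.5 x (1-t^2) c (1 + 3*0.044715 x^2)
            dinner = 0.134145 * x2
            dinner += 1.0
            dinner *= _GELU_C
            u = 1.0 - t * t
            u *= x
            u *= dinner
            u += 1.0 + t
            u *= 0.5
            u *= out.grad
            a._accumulate(u, fresh=True)
        return run
    return _make(y, (a,), bw)


# -- shape ops ------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    def bw(out):
        def run():
            a._accumulate(out.grad.reshape(a.data.shape))
        return run
    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def bw(out):
        def run():
            a._accumulate(out.grad.transpose(inv))
        return run
    return _make(a.data.transpose(axes), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def run():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * out.grad.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(idx)])
        return run
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, bw)


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy()
                          if np.ndim(g) else np.full_like(a.data, g))
        return run
    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]

    def bw(out):
        def run():
            g = out.grad / n
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy()
                          if np.ndim(g) else np.full_like(a.data, g))
        return run
    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), bw)


# -- fused kernels --------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            g = out.grad
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))
        return run
    return _make(a.data @ b.data, (a, b), bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map over the last axis: ``x @ w + b`` with fused backward."""
    y = x.data @ w.data
    if b is not None:
        np.add(y, b.data, out=y)
    parents = (x, w) if b is None else (x, w, b)

    def bw(out):
        def run():
            g = out.grad
            g2 = g.reshape(-1, g.shape[-1])
            x2 = x.data.reshape(-1, x.data.shape[-1])
            if w.requires_grad:
                w._accumulate(x2.T @ g2, fresh=True)
            if b is not None and b.requires_grad:
                b._accumulate(g2.sum(axis=0), fresh=True)
            if x.requires_grad:
                x._accumulate((g2 @ w.data.T).reshape(x.data.shape),
                              fresh=True)
        return run
    return _make(y, parents, bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(out):
        def run():
            g = out.grad
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))
        return run
    return _make(s, (a,), bw)


def attention(q: Tensor, k: Tensor, v: Tensor,
              mask_add: np.ndarray | None = None) -> Tensor:
    """Scaled dot-product attention with an additive mask (fused).

    q, k, v: (..., T, dk); mask_add broadcastable to (..., T, T) with 0 for
    visible keys and a large negative number for masked ones.
    """
    dk = q.data.shape[-1]
    scale = 1.0 / float(np.sqrt(dk))
    scores = (q.data @ np.swapaxes(k.data, -1, -2)) * scale
    if mask_add is not None:
        scores = scores + mask_add
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    out_data = attn @ v.data

    def bw(out):
        def run():
            g = out.grad
            if v.requires_grad:
                v._accumulate(np.swapaxes(attn, -1, -2) @ g)
            da = g @ np.swapaxes(v.data, -1, -2)
            ds = attn * (da - (da * attn).sum(axis=-1, keepdims=True))
            ds *= scale
            if q.requires_grad:
                q._accumulate(ds @ k.data)
            if k.requires_grad:
                k._accumulate(np.swapaxes(ds, -1, -2) @ q.data)
        return run
    return _make(out_data, (q, k, v), bw)


def qkv_attention(qkv: Tensor, n_heads: int,
                  mask_add: np.ndarray | None = None) -> Tensor:
    """Multi-head self-attention from a packed (B, T, 3*D) projection.

    Splits into heads, applies scaled dot-product attention with an optional
    additive key mask, and returns the merged (B, T, D) context. One fused
    kernel keeps the per-layer op count (and allocation traffic) low.
    """
    B, T, threeD = qkv.data.shape
    D = threeD // 3
    dh = D // n_heads
    scale = 1.0 / float(np.sqrt(dh))
    parts = qkv.data.reshape(B, T, 3, n_heads, dh).transpose(2, 0, 3, 1, 4)
    q, k, v = np.ascontiguousarray(parts)  # (B, H, T, dh) each
    scores = (q @ k.swapaxes(-1, -2)) * scale
    if mask_add is not None:
        scores += mask_add
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    attn = scores
    ctx = attn @ v                                   # (B, H, T, dh)
    out_data = np.ascontiguousarray(ctx.transpose(0, 2, 1, 3)).reshape(B, T, D)

    def bw(out):
        def run():
            g = out.grad.reshape(B, T, n_heads, dh).transpose(0, 2, 1, 3)
            gv = attn.swapaxes(-1, -2) @ g
            da = g @ v.swapaxes(-1, -2)
            ds = attn * (da - (da * attn).sum(axis=-1, keepdims=True))
            ds *= scale
            gq = ds @ k
            gk = ds.swapaxes(-1, -2) @ q
            gqkv = np.empty((3, B, n_heads, T, dh), dtype=gq.dtype)
            gqkv[0], gqkv[1], gqkv[2] = gq, gk, gv
            qkv._accumulate(np.ascontiguousarray(
                gqkv.transpose(1, 3, 0, 2, 4)).reshape(B, T, threeD),
                fresh=True)
        return run
    return _make(out_data, (qkv,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5, residual: Tensor | None = None) -> Tensor:
    """Layer normalisation over the last axis (fused backward).

    With ``residual`` given, normalises ``x + residual`` and routes the
    input gradient to both (the transformer's post-norm residual block).
    """
    xin = x.data if residual is None else x.data + residual.data
    mu = xin.mean(axis=-1, keepdims=True)
    xc = xin - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * gamma.data + beta.data
    d = xin.shape[-1]
    parents = (x, gamma, beta) if residual is None \
        else (x, residual, gamma, beta)

    def bw(out):
        def run():
            g = out.grad
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).reshape(-1, d).sum(axis=0),
                                  fresh=True)
            if beta.requires_grad:
                beta._accumulate(g.reshape(-1, d).sum(axis=0), fresh=True)
            gx = g * gamma.data
            t1 = gx.mean(axis=-1, keepdims=True)
            t2 = (gx * xhat).mean(axis=-1, keepdims=True)
            gx -= t1
            gx -= xhat * t2
            gx *= inv
            if residual is not None and residual.requires_grad:
                residual._accumulate(gx)  # shares gx: copy, not fresh
            if x.requires_grad:
                x._accumulate(gx, fresh=True)
        return run
    return _make(y, parents, bw)


def masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over the time axis restricted to mask==1.

    x: (B, T, D); mask: (B, T) in {0, 1}. Every row must have >=1 valid step.
    """
    m = np.asarray(mask, dtype=x.data.dtype)
    counts = m.sum(axis=1, keepdims=True)  # (B, 1)
    y = (x.data * m[:, :, None]).sum(axis=1) / counts

    def bw(out):
        def run():
            g = out.grad / counts  # (B, D)
            x._accumulate(g[:, None, :] * m[:, :, None], fresh=True)
        return run
    return _make(y, (x,), bw)


def mask_scale(x: Tensor, mask: np.ndarray) -> Tensor:
    """Multiply by a constant (non-differentiated) array, broadcasting."""
    m = np.asarray(mask, dtype=x.data.dtype)

    def bw(out):
        def run():
            x._accumulate(out.grad * m, fresh=True)
        return run
    return _make(x.data * m, (x,), bw)


def pair_products(x: Tensor, idx_i: np.ndarray, idx_j: np.ndarray) -> Tensor:
    """All elementwise channel products x[..., i]*x[..., j] for given pairs."""
    y = x.data[..., idx_i] * x.data[..., idx_j]

    def bw(out):
        def run():
            g = out.grad
            gx = np.zeros_like(x.data)
            # C(C+1)/2 pairs; loop is over channels, not samples
            for p in range(len(idx_i)):
                gx[..., idx_i[p]] += g[..., p] * x.data[..., idx_j[p]]
                gx[..., idx_j[p]] += g[..., p] * x.data[..., idx_i[p]]
            x._accumulate(gx, fresh=True)
        return run
    return _make(y, (x,), bw)


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup into a learnable table; idx is an integer array."""
    idx = np.asarray(idx)

    def bw(out):
        def run():
            if table.requires_grad:
                gt = np.zeros_like(table.data)
                np.add.at(gt, idx.reshape(-1),
                          out.grad.reshape(-1, table.data.shape[-1]))
                table._accumulate(gt)
        return run
    return _make(table.data[idx], (table,), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against row softmax (fused)."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()

    def bw(out):
        def run():
            g = p.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accumulate(out.grad * g / n, fresh=True)
        return run
    return _make(np.asarray(nll, dtype=logits.data.dtype), (logits,), bw)


def conv3d_same(x: Tensor, w: Tensor, b: Tensor, kernel: int = 3) -> Tensor:
    """3-D convolution with 'same' zero padding and stride 1 (fused).

    x: (B, D1, D2, D3, Cin); w: (k^3 * Cin, Cout); b: (Cout,).
    The kernel axes are unrolled in C order (o1, o2, o3, cin).
    """
    kk = kernel
    pad = kk // 2
    B, d1, d2, d3, cin = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    cols = np.empty((B, d1, d2, d3, kk * kk * kk * cin), dtype=x.data.dtype)
    p = 0
    for o1 in range(kk):
        for o2 in range(kk):
            for o3 in range(kk):
                cols[..., p * cin:(p + 1) * cin] = \
                    xp[:, o1:o1 + d1, o2:o2 + d2, o3:o3 + d3, :]
                p += 1
    y = cols @ w.data + b.data

    def bw(out):
        def run():
            g = out.grad
            g2 = g.reshape(-1, g.shape[-1])
            if w.requires_grad:
                w._accumulate(cols.reshape(-1, cols.shape[-1]).T @ g2)
            if b.requires_grad:
                b._accumulate(g2.sum(axis=0))
            if x.requires_grad:
                dcols = (g2 @ w.data.T).reshape(cols.shape)
                gxp = np.zeros_like(xp)
                p = 0
                for o1 in range(kk):
                    for o2 in range(kk):
                        for o3 in range(kk):
                            gxp[:, o1:o1 + d1, o2:o2 + d2, o3:o3 + d3, :] += \
                                dcols[..., p * cin:(p + 1) * cin]
                            p += 1
                x._accumulate(gxp[:, pad:pad + d1, pad:pad + d2,
                                  pad:pad + d3, :])
        return run
    return _make(y, (x, w, b), bw)
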