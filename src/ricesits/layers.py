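"""Neural-network building blocks on top of :mod:`ricesits.autodiff`.

Modules follow the familiar layer API: parameters are discovered by walking
attributes, ``train()``/``eval()`` toggle dropout, and ``named_parameters``
gives the deterministic flat naming used by checkpoints.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        for name in sorted(vars(self)):
            v = getattr(self, name)
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name in sorted(vars(self)):
            v = getattr(self, name)
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self):
        self.training = True
        for _, m in self.modules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for _, m in self.modules():
            m.eval()
        return self

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(xavier_uniform(rng, n_in, n_out))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor, residual: Tensor | None = None) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps, residual)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws from a shared rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        u = self.rng.random(x.shape, dtype=np.float32)
        mask = (u < keep).astype(x.data.dtype)
        mask /= keep
        return ad.mask_scale(x, mask)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, mask_add: np.ndarray | None) -> Tensor:
        ctx = ad.qkv_attention(self.qkv(x), self.n_heads, mask_add)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHSA + residual + LN, FF(GELU) + residual + LN."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor, mask_add: np.ndarray | None) -> Tensor:
        h = self.norm1(self.drop1(self.attn(x, mask_add)), residual=x)
        ff = self.ff2(ad.gelu(self.ff1(h)))
        return self.norm2(self.drop2(ff), residual=h)


class EmbeddingTable(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = Parameter(rng.normal(0.0, 0.02, size=(n_rows, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ad.embedding(self.table, idx)


# -- optimisation ----------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.
    """
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float(np.vdot(g, g))
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for g in grads:
            g *= scale
    return norm
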