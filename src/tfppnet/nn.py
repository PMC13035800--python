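"""Neural-network building blocks used by the seizure classifier.

Layers are thin objects holding :class:`~tfppnet.autograd.Parameter` weights;
``forward`` takes a :class:`Context` carrying the training flag and the RNG
that drives dropout, so evaluation is deterministic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "Context", "Module", "Linear", "LayerNorm", "InstanceNorm", "Dropout",
    "MultiHeadAttention", "SKAttention", "Adam", "glorot_uniform",
]


@dataclass
class Context:
    """Per-forward runtime state (training flag + dropout RNG)."""
    training: bool = False
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))


def glorot_uniform(rng: np.random.Generator, shape, fan_in=None, fan_out=None):
    fan_in = fan_in if fan_in is not None else shape[0]
    fan_out = fan_out if fan_out is not None else shape[-1]
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base class: parameter traversal, train/eval mode, state dicts."""

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {own[name].data.shape} vs {arr.shape}")
            own[name].data = arr.astype(own[name].data.dtype).copy()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        self.weight = Parameter(glorot_uniform(rng, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalization over the last axis with learnable affine."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(d, dtype=np.float32))
        self.bias = Parameter(np.zeros(d, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gain + self.bias


class InstanceNorm(Module):
    """Per-(sample, feature-map) normalization over the time axis.

    Input (N, C, T): each row is standardized over T, then scaled/shifted by a
    learnable per-map affine. Deterministic at eval time (no running stats),
    which keeps seeded runs bit-reproducible.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones((c, 1), dtype=np.float32))
        self.bias = Parameter(np.zeros((c, 1), dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gain + self.bias


class Dropout(Module):
    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x: Tensor, ctx: Context) -> Tensor:
        return x.dropout(self.p, ctx.rng, ctx.training)


class MultiHeadAttention(Module):
    """Standard scaled dot-product multi-head self-attention."""

    def __init__(self, rng, d_model: int, n_heads: int):
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(rng, d_model, 3 * d_model)
        self.out_proj = Linear(rng, d_model, d_model)
        self.last_attention: np.ndarray | None = None  # (N, H, L, L), detached

    def forward(self, x: Tensor) -> Tensor:
        n, l, d = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv.forward(x)                              # (N, L, 3d)
        qkv = qkv.reshape(n, l, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, N, H, L, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)                         # (N, H, L, L)
        self.last_attention = attn.data.copy()
        mixed = attn @ v                                       # (N, H, L, dh)
        mixed = mixed.transpose(0, 2, 1, 3).reshape(n, l, d)
        return self.out_proj.forward(mixed)


class SKAttention(Module):
    """Selective-kernel attention over a token sequence.

    M parallel depthwise convolutions (one per kernel size) run along the
    token axis; their sum is pooled into a global descriptor, squeezed
    through a bottleneck, and expanded into per-branch, per-feature softmax
    weights that convexly combine the branch outputs.
    """

    def __init__(self, rng, d_model: int, kernel_sizes, reduction: int = 4):
        kernel_sizes = tuple(int(k) for k in kernel_sizes)
        if len(kernel_sizes) < 2:
            raise ValueError("selective-kernel attention needs at least 2 branch kernel sizes")
        if any(k % 2 == 0 for k in kernel_sizes):
            raise ValueError(f"branch kernel sizes must be odd, got {kernel_sizes}")
        self.kernel_sizes = kernel_sizes
        d_hidden = max(d_model // reduction, 4)
        self.branch_weights = [
            Parameter(glorot_uniform(rng, (d_model, k), fan_in=k, fan_out=k))
            for k in kernel_sizes
        ]
        self.squeeze = Linear(rng, d_model, d_hidden)
        self.expand = [Linear(rng, d_hidden, d_model) for _ in kernel_sizes]
        self.last_branch_weights: np.ndarray | None = None  # (N, M, d), detached

    def branch_outputs(self, x: Tensor):
        """x: (N, L, d) -> list of M tensors (N, L, d)."""
        xt = x.transpose(0, 2, 1)  # (N, d, L): convolve along tokens
        return [xt.depthwise_conv1d_same(w).transpose(0, 2, 1)
                for w in self.branch_weights]

    def fuse(self, branches) -> Tensor:
        """Softmax-weighted convex combination of branch outputs."""
        if len(branches) < 2:
            raise ValueError("selective-kernel fusion needs at least 2 branches")
        total = branches[0]
        for b in branches[1:]:
            total = total + b
        desc = total.mean(axis=1)                      # (N, d) global average
        hidden = self.squeeze.forward(desc).elu()
        logits = concat([lin.forward(hidden).reshape(desc.shape[0], 1, -1)
                         for lin in self.expand], axis=1)   # (N, M, d)
        weights = logits.softmax(axis=1)
        self.last_branch_weights = weights.data.copy()
        out = None
        for m, b in enumerate(branches):
            contrib = b * weights[:, m:m + 1, :]       # broadcast over tokens
            out = contrib if out is None else out + contrib
        return out

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(self.branch_outputs(x))


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999), matching the training protocol
    of lr=1e-3 used throughout."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
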