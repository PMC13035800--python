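"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core on which the seizure classifier is built. It
implements a define-by-run tape: every operation on a :class:`Tensor`
records its inputs and a backward closure; :meth:`Tensor.backward` walks
the graph in reverse topological order and accumulates gradients.

Only the operations the network needs are provided, each with an explicit
vector-Jacobian product. Every primitive is verified against central
finite differences in the test suite, so the engine is trustworthy without
being general. All floating point work is float64 unless the caller passes
float32 data (training uses float32 for memory).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "cross_entropy_with_logits"]


def _as_array(x, dtype=None):
    a = np.asarray(x)
    if dtype is not None and a.dtype != dtype:
        a = a.astype(dtype)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str = ""):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = tuple(_parents)
        self.name = name

    # -- basic introspection -------------------------------------------------
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
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name!r})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- graph machinery -----------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # reverse topological order
        topo, seen = [], set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if node.requires_grad and node._backward is None and g is not None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves reached through grads dict (no backward of their own)
        for node in topo:
            if node._backward is None and node.requires_grad and id(node) in grads:
                g = grads.pop(id(node))
                node.grad = g if node.grad is None else node.grad + g

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _lift(x, like=None):
        if isinstance(x, Tensor):
            return x
        if like is not None and np.isscalar(x):
            return Tensor(np.asarray(x, dtype=like))
        return Tensor(x)

    def __add__(self, other):
        other = self._lift(other, like=self.dtype)
        out_data = self.data + other.data

        def backward(g):
            return ((self, _unbroadcast(g, self.shape)),
                    (other, _unbroadcast(g, other.shape)))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other, like=self.dtype)
        out_data = self.data * other.data

        def backward(g):
            return ((self, _unbroadcast(g * other.data, self.shape)),
                    (other, _unbroadcast(g * self.data, other.shape)))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other, like=self.dtype)
        out_data = self.data / other.data

        def backward(g):
            return ((self, _unbroadcast(g / other.data, self.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires ndim >= 2 operands")

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, self.shape)),
                    (other, _unbroadcast(gb, other.shape)))

        return self._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            return ((self, g.reshape(old)),)

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            full = np.zeros(shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            return ((self, full),)

        return self._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).copy()),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(gg, shape).copy()),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------
    def elu(self, alpha: float = 1.0):
        x = self.data
        out_data = np.where(x > 0, x, alpha * np.expm1(x))

        def backward(g):
            return ((self, g * np.where(x > 0, 1.0, alpha * np.exp(x))),)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return ((self, g * out_data),)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            return ((self, g / self.data),)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return ((self, g * 0.5 / out_data),)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis`."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return ((self, out_data * (g - dot)),)

        return self._make(out_data, (self,), backward)

    # -- structured primitives for the conv layers --------------------------
    def conv1d_same(self, weight: "Tensor"):
        """Cross-correlation along the last axis with 'same' zero padding.

        self: (N, Cin, T); weight: (Cout, Cin, K). Returns (N, Cout, T) with
        out[n,o,t] = sum_{c,k} xpad[n,c,t+k] w[o,c,k], where xpad pads
        (K-1)//2 left (one extra left for even K). FFT-based so long temporal
        kernels stay cheap.
        """
        from scipy import fft as sfft  # preserves float32, fast non-pow2 sizes

        x, w = self.data, weight.data
        n, cin, t = x.shape
        cout, cin2, k = w.shape
        if cin != cin2:
            raise ValueError(f"channel mismatch: input {cin} vs weight {cin2}")
        pad_l = k // 2 if k % 2 == 0 else (k - 1) // 2
        lfull = t + k - 1
        nfft = sfft.next_fast_len(lfull, real=True)
        xf = sfft.rfft(x, n=nfft)                        # (N, Cin, F)
        wf = sfft.rfft(w[:, :, ::-1].astype(x.dtype), n=nfft)  # flip => correlation
        yfull = sfft.irfft(np.einsum("ncf,ocf->nof", xf, wf), n=nfft)[..., :lfull]
        # corr(xpad, w)[t] = conv(x, flip(w))[t + k - 1 - pad_l]
        s0 = k - 1 - pad_l
        out_data = np.ascontiguousarray(yfull[..., s0:s0 + t])

        def backward(g):
            g = g.astype(x.dtype, copy=False)
            # dxpad = conv(g, w); dx = dxpad[pad_l : pad_l + t]
            gf = sfft.rfft(g, n=nfft)
            wf2 = sfft.rfft(w.astype(x.dtype, copy=False), n=nfft)
            dxfull = sfft.irfft(np.einsum("nof,ocf->ncf", gf, wf2), n=nfft)[..., :lfull]
            dx = np.ascontiguousarray(dxfull[..., pad_l:pad_l + t])
            # dw[o,c,k'] = sum_{n,t} xpad[n,c,t+k'] g[n,o,t] = corr(xpad, g)[k']
            #            = conv(xpad, flip(g))[k' + t - 1]
            nfft2 = sfft.next_fast_len(lfull + t - 1, real=True)
            xpad = np.pad(x, ((0, 0), (0, 0), (pad_l, (k - 1) - pad_l)))
            xpf = sfft.rfft(xpad, n=nfft2)
            gfl = sfft.rfft(g[..., ::-1], n=nfft2)
            dwfull = sfft.irfft(np.einsum("ncf,nof->ocf", xpf, gfl), n=nfft2)
            dw = np.ascontiguousarray(dwfull[..., t - 1:t - 1 + k]).astype(w.dtype)
            return ((self, dx), (weight, dw))

        return self._make(out_data, (self, weight), backward)

    def depthwise_conv1d_same(self, weight: "Tensor"):
        """Per-channel cross-correlation along the last axis, 'same' padding.

        self: (N, C, T); weight: (C, K) with K odd. Returns (N, C, T).
        """
        x, w = self.data, weight.data
        n, c, t = x.shape
        c2, k = w.shape
        if c != c2:
            raise ValueError(f"channel mismatch: input {c} vs weight {c2}")
        if k % 2 != 1:
            raise ValueError("depthwise kernels must be odd-length")
        pad = (k - 1) // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        windows = np.lib.stride_tricks.sliding_window_view(xpad, k, axis=-1)
        out_data = np.einsum("nctk,ck->nct", windows, w).astype(x.dtype)

        def backward(g):
            gpad = np.pad(g, ((0, 0), (0, 0), (pad, pad)))
            gwin = np.lib.stride_tricks.sliding_window_view(gpad, k, axis=-1)
            dx = np.einsum("nctk,ck->nct", gwin, w[:, ::-1]).astype(x.dtype)
            dw = np.einsum("nctk,nct->ck", windows, g).astype(w.dtype)
            return ((self, dx), (weight, dw))

        return self._make(out_data, (self, weight), backward)

    def spatial_collapse(self, weight: "Tensor"):
        """Depthwise spatial convolution collapsing the electrode axis.

        self: (N, F, E, T); weight: (F, D, E). Output (N, F*D, T) where
        out[n, f*D+d, t] = sum_e x[n, f, e, t] * w[f, d, e].
        """
        x, w = self.data, weight.data
        n, f, e, t = x.shape
        f2, d, e2 = w.shape
        if (f, e) != (f2, e2):
            raise ValueError(f"shape mismatch: input (F={f},E={e}) vs weight (F={f2},E={e2})")
        out = np.einsum("nfet,fde->nfdt", x, w).reshape(n, f * d, t).astype(x.dtype)

        def backward(g):
            gr = g.reshape(n, f, d, t)
            dx = np.einsum("nfdt,fde->nfet", gr, w).astype(x.dtype)
            dw = np.einsum("nfdt,nfet->fde", gr, x).astype(w.dtype)
            return ((self, dx), (weight, dw))

        return self._make(out, (self, weight), backward)

    def avg_pool1d(self, pool: int):
        """Average pooling along the last axis; trailing remainder dropped."""
        x = self.data
        t = x.shape[-1]
        tq = (t // pool) * pool
        lead = x.shape[:-1]
        out_data = x[..., :tq].reshape(*lead, tq // pool, pool).mean(axis=-1)

        def backward(g):
            dx = np.zeros_like(x)
            dx[..., :tq] = np.repeat(g, pool, axis=-1) / pool
            return ((self, dx),)

        return self._make(out_data, (self,), backward)

    def dropout(self, p: float, rng: np.random.Generator, training: bool):
        if not training or p <= 0:
            return self
        mask = (rng.random(self.shape) >= p).astype(self.data.dtype) / (1.0 - p)

        def backward(g):
            return ((self, g * mask),)

        return self._make(self.data * mask, (self,), backward)


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data, name: str = ""):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True, name=name)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, differentiable."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            outs.append((t, g[tuple(idx)]))
        return tuple(outs)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy. labels: int array (N,)."""
    z = logits.data
    n = z.shape[0]
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    picked = z[np.arange(n), labels]
    loss_val = float(np.mean(lse - picked))

    def backward(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(n), labels] -= 1.0
        return ((logits, g * p / n),)

    out = Tensor(loss_val)
    if logits.requires_grad:
        out.requires_grad = True
        out._parents = (logits,)
        out._backward = backward
    return out
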