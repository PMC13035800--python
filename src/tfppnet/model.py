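"""SeizureTransNet: hybrid CNN / Transformer classifier for EEG segments.

The network has two input streams feeding one token sequence:

* **EEG stream** — an EEGNet-style convolutional extractor: a temporal
  convolution along time, a depthwise spatial convolution that collapses
  the electrode axis, and two depthwise-separable convolution blocks, with
  average pooling and dropout between layers. The pooled feature maps are
  projected to ``d_model``-dimensional tokens (one per remaining time step).
* **Connectivity stream** — each slice of the segment's connectivity stack
  (PP / |PCC| / PLV matrices over time sub-windows and bands) is flattened
  and linearly projected to one token.

A learnable class token is prepended, learnable positional encodings are
added, and the sequence passes through pre-norm Transformer encoder blocks
whose feed-forward stage is selective-kernel (SK) attention: multi-branch
depthwise convolutions over the token axis, convexly re-weighted per
feature by a learned softmax. The final class-token state goes through a
small MLP head (norm, linear, ELU, dropout, linear) to two class scores.

``input_mode`` selects the streams, reproducing the ablation inputs:
raw EEG only, EEG plus a single-network stack (|PCC| or PLV), or EEG plus
the fused TFPP stack.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Parameter, Tensor, concat
from .nn import (
    Context, Dropout, InstanceNorm, LayerNorm, Linear, Module,
    MultiHeadAttention, SKAttention, glorot_uniform,
)

__all__ = ["ModelConfig", "SeizureTransNet", "EncoderBlock", "CNNExtractor"]

INPUT_MODES = ("eeg", "eeg+pcc", "eeg+plv", "eeg+tfpp")


@dataclass
class ModelConfig:
    """Hyperparameters of SeizureTransNet (EEGNet-style defaults)."""

    input_mode: str = "eeg+tfpp"
    n_channels: int = 18
    samples_per_segment: int = 1024
    n_tfpp_slices: int = 7
    temporal_kernel_len: int = 64
    n_temporal_filters: int = 8
    depth_multiplier: int = 2
    sep_kernel_len: int = 15
    pool_sizes: tuple = (4, 8)
    dropout_cnn: float = 0.25
    d_model: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    sk_kernel_sizes: tuple = (3, 5)
    dropout_head: float = 0.5
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}, got {self.input_mode!r}")
        if self.d_model % self.n_heads != 0:
            raise ValueError(f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")
        if any(p < 1 for p in self.pool_sizes) or len(self.pool_sizes) != 2:
            raise ValueError(f"pool_sizes must be a pair of integers >= 1, got {self.pool_sizes}")
        if any(k % 2 == 0 for k in self.sk_kernel_sizes):
            raise ValueError(f"sk_kernel_sizes must be odd, got {self.sk_kernel_sizes}")
        if self.sep_kernel_len % 2 == 0:
            raise ValueError(f"sep_kernel_len must be odd, got {self.sep_kernel_len}")
        if self.samples_per_segment % (self.pool_sizes[0] * self.pool_sizes[1]) != 0:
            raise ValueError(
                f"samples_per_segment={self.samples_per_segment} must be divisible by "
                f"pool_sizes product {self.pool_sizes[0] * self.pool_sizes[1]}")

    @property
    def uses_connectivity(self) -> bool:
        return self.input_mode != "eeg"

    @property
    def n_eeg_tokens(self) -> int:
        return self.samples_per_segment // (self.pool_sizes[0] * self.pool_sizes[1])

    @property
    def n_tokens(self) -> int:
        n = self.n_eeg_tokens
        if self.uses_connectivity:
            n += self.n_tfpp_slices
        return n

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pool_sizes"] = list(self.pool_sizes)
        d["sk_kernel_sizes"] = list(self.sk_kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "pool_sizes" in d:
            d["pool_sizes"] = tuple(d["pool_sizes"])
        if "sk_kernel_sizes" in d:
            d["sk_kernel_sizes"] = tuple(d["sk_kernel_sizes"])
        return cls(**d)


class CNNExtractor(Module):
    """Temporal conv -> spatial collapse -> two depthwise-separable blocks.

    Conv layers carry no bias (normalization layers follow them), so an
    all-zero input yields all-zero pre-activation conv outputs.
    """

    def __init__(self, rng, cfg: ModelConfig):
        f, d = cfg.n_temporal_filters, cfg.depth_multiplier
        e, kt, ks = cfg.n_channels, cfg.temporal_kernel_len, cfg.sep_kernel_len
        c = f * d
        self.cfg = cfg
        self.temporal_weight = Parameter(glorot_uniform(rng, (f, 1, kt), fan_in=kt, fan_out=kt))
        self.spatial_weight = Parameter(glorot_uniform(rng, (f, d, e), fan_in=e, fan_out=e))
        self.norm_spatial = InstanceNorm(c)
        self.dw1 = Parameter(glorot_uniform(rng, (c, ks), fan_in=ks, fan_out=ks))
        self.pw1 = Linear(rng, c, c, bias=False)
        self.norm1 = InstanceNorm(c)
        self.dw2 = Parameter(glorot_uniform(rng, (c, ks), fan_in=ks, fan_out=ks))
        self.pw2 = Linear(rng, c, c, bias=False)
        self.norm2 = InstanceNorm(c)
        self.drop = Dropout(cfg.dropout_cnn)
        self.n_feature_maps = c

    def _pointwise(self, x: Tensor, lin: Linear) -> Tensor:
        return lin.forward(x.transpose(0, 2, 1)).transpose(0, 2, 1)

    def forward(self, x: Tensor, ctx: Context) -> Tensor:
        """x: (B, E, T) -> feature maps (B, F*D, T / (p1*p2))."""
        b, e, t = x.shape
        cfg = self.cfg
        if (e, t) != (cfg.n_channels, cfg.samples_per_segment):
            raise ValueError(
                f"expected input (B, {cfg.n_channels}, {cfg.samples_per_segment}), "
                f"got (B, {e}, {t})")
        p1, p2 = cfg.pool_sizes
        h = x.reshape(b * e, 1, t).conv1d_same(self.temporal_weight)   # (B*E, F, T)
        h = h.reshape(b, e, cfg.n_temporal_filters, t).transpose(0, 2, 1, 3)  # (B,F,E,T)
        h = h.spatial_collapse(self.spatial_weight)                    # (B, F*D, T)
        h = self.norm_spatial.forward(h).elu().avg_pool1d(p1)
        h = self.drop.forward(h, ctx)
        h = self._pointwise(h.depthwise_conv1d_same(self.dw1), self.pw1)
        h = self.norm1.forward(h).elu()
        h = self.drop.forward(h, ctx)
        h = self._pointwise(h.depthwise_conv1d_same(self.dw2), self.pw2)
        h = self.norm2.forward(h).elu().avg_pool1d(p2)
        h = self.drop.forward(h, ctx)
        return h

    def separable_parameter_count(self) -> int:
        """Parameters of the two depthwise-separable blocks."""
        return int(self.dw1.size + self.pw1.weight.size
                   + self.dw2.size + self.pw2.weight.size)

    def dense_equivalent_parameter_count(self) -> int:
        """Parameters two dense convolutions of the same receptive field
        (C in, C out, kernel sep_kernel_len) would need."""
        c, k = self.n_feature_maps, self.cfg.sep_kernel_len
        return int(2 * c * c * k)


class EncoderBlock(Module):
    """Pre-norm Transformer block: multi-head attention, then an SK-attention
    feed-forward stage, each with a residual connection."""

    def __init__(self, rng, cfg: ModelConfig):
        d = cfg.d_model
        self.ln_attn = LayerNorm(d)
        self.attn = MultiHeadAttention(rng, d, cfg.n_heads)
        self.ln_sk = LayerNorm(d)
        self.sk = SKAttention(rng, d, cfg.sk_kernel_sizes)
        self.sk_out = Linear(rng, d, d)
        self.drop = Dropout(cfg.dropout_head * 0.5)

    def forward(self, tokens: Tensor, ctx: Context) -> Tensor:
        h = tokens + self.drop.forward(
            self.attn.forward(self.ln_attn.forward(tokens)), ctx)
        ff = self.sk_out.forward(self.sk.forward(self.ln_sk.forward(h)))
        return h + self.drop.forward(ff, ctx)


class SeizureTransNet(Module):
    """The full classifier. See the module docstring for the architecture."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.cnn = CNNExtractor(rng, cfg)
        self.eeg_proj = Linear(rng, self.cnn.n_feature_maps, cfg.d_model)
        if cfg.uses_connectivity:
            self.tfpp_proj = Linear(rng, cfg.n_channels * cfg.n_channels, cfg.d_model)
        self.class_token = Parameter(
            rng.normal(0, 0.02, size=(1, 1, cfg.d_model)).astype(np.float32))
        self.pos_embedding = Parameter(
            rng.normal(0, 0.02, size=(1, cfg.n_tokens + 1, cfg.d_model)).astype(np.float32))
        self.blocks = [EncoderBlock(rng, cfg) for _ in range(cfg.n_encoder_layers)]
        self.head_norm = LayerNorm(cfg.d_model)
        self.head_hidden = Linear(rng, cfg.d_model, cfg.d_model)
        self.head_drop = Dropout(cfg.dropout_head)
        self.head_out = Linear(rng, cfg.d_model, cfg.n_classes)
        self.dropout_rng = np.random.default_rng(cfg.seed + 1)

    # -- token assembly ------------------------------------------------------
    def tokenize(self, x: Tensor, tfpp: Tensor | None, ctx: Context) -> Tensor:
        cfg = self.cfg
        feats = self.cnn.forward(x, ctx)                    # (B, C, T')
        tokens = self.eeg_proj.forward(feats.transpose(0, 2, 1))  # (B, T', d)
        if cfg.uses_connectivity:
            if tfpp is None:
                raise ValueError(
                    f"input_mode {cfg.input_mode!r} requires a connectivity stack per segment")
            b, s, c1, c2 = tfpp.shape
            if s != cfg.n_tfpp_slices or (c1, c2) != (cfg.n_channels, cfg.n_channels):
                raise ValueError(
                    f"expected connectivity stack (B, {cfg.n_tfpp_slices}, "
                    f"{cfg.n_channels}, {cfg.n_channels}), got {tfpp.shape}")
            aux = self.tfpp_proj.forward(tfpp.reshape(b, s, c1 * c2))  # (B, S, d)
            tokens = concat([tokens, aux], axis=1)
        elif tfpp is not None:
            raise ValueError("input_mode 'eeg' takes no connectivity input")
        b = tokens.shape[0]
        cls = self.class_token + Tensor(np.zeros((b, 1, cfg.d_model), dtype=np.float32))
        tokens = concat([cls, tokens], axis=1)
        return tokens + self.pos_embedding

    # -- public API ----------------------------------------------------------
    def forward(self, x, tfpp=None, training: bool = False) -> Tensor:
        """Class scores (logits), shape (B, n_classes).

        x: (B, E, T) array; tfpp: (B, S, C, C) array when the input mode
        carries a connectivity stream. Deterministic in eval mode.
        """
        ctx = Context(training=training, rng=self.dropout_rng)
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 4 and x.shape[1] == 1:   # tolerate (B, 1, E, T)
            x = x.reshape(x.shape[0], x.shape[2], x.shape[3])
        if tfpp is not None and not isinstance(tfpp, Tensor):
            tfpp = Tensor(np.asarray(tfpp, dtype=np.float32))
        tokens = self.tokenize(x, tfpp, ctx)
        for block in self.blocks:
            tokens = block.forward(tokens, ctx)
        cls = tokens[:, 0, :]
        h = self.head_hidden.forward(self.head_norm.forward(cls)).elu()
        h = self.head_drop.forward(h, ctx)
        return self.head_out.forward(h)

    def predict_proba(self, x, tfpp=None, batch_size: int = 256) -> np.ndarray:
        """Eval-mode softmax probabilities, shape (N, n_classes)."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            tf_b = None if tfpp is None else tfpp[i:i + batch_size]
            logits = self.forward(x[i:i + batch_size], tf_b, training=False)
            out.append(logits.softmax(axis=-1).data)
        return np.concatenate(out, axis=0)

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        import json
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "SeizureTransNet":
        import json
        z = np.load(path, allow_pickle=False)
        cfg = ModelConfig.from_dict(json.loads(bytes(z["config_json"]).decode()))
        model = cls(cfg)
        model.load_state_dict(
            {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")})
        return model
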