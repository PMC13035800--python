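"""Architecture contracts of the CNN/Transformer classifier."""

import numpy as np
import pytest

from tfppnet import ModelConfig, SeizureTransNet
from tfppnet.autograd import Tensor, cross_entropy_with_logits
from tfppnet.nn import Context, SKAttention

from conftest import reduced_model_config


def small_cfg(mode="eeg+tfpp", **kw):
    base = dict(input_mode=mode, n_channels=6, samples_per_segment=256,
                n_tfpp_slices=0 if mode == "eeg" else 4, n_temporal_filters=4,
                depth_multiplier=2, d_model=16, n_heads=2, n_encoder_layers=1,
                pool_sizes=(4, 8), sk_kernel_sizes=(3, 5), seed=7)
    base.update(kw)
    return ModelConfig(**base)


def batch(cfg, n=4, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, cfg.n_channels, cfg.samples_per_segment)).astype(np.float32)
    a = None
    if cfg.uses_connectivity:
        a = rng.random((n, cfg.n_tfpp_slices, cfg.n_channels,
                        cfg.n_channels)).astype(np.float32)
    return x, a


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kw,msg", [
    (dict(d_model=30, n_heads=4), "divisible"),
    (dict(sk_kernel_sizes=(2, 4)), "odd"),
    (dict(sep_kernel_len=8), "odd"),
    (dict(pool_sizes=(0, 4)), "pool_sizes"),
    (dict(input_mode="magic"), "input_mode"),
    (dict(samples_per_segment=100), "divisible"),
])
def test_config_validation(kw, msg):
    with pytest.raises(ValueError, match=msg):
        small_cfg(**kw)


# ---------------------------------------------------------------------------
# CNN extractor
# ---------------------------------------------------------------------------

def test_token_axis_length_follows_pooling():
    """4 x 1 x 18 x 1024 with pools (4, 8) -> 32 tokens."""
    cfg = ModelConfig(input_mode="eeg", n_channels=18, samples_per_segment=1024,
                      n_tfpp_slices=0, pool_sizes=(4, 8), seed=0)
    model = SeizureTransNet(cfg)
    x = Tensor(np.zeros((4, 18, 1024), dtype=np.float32))
    feats = model.cnn.forward(x + Tensor(np.random.default_rng(0)
                                         .normal(size=(4, 18, 1024)).astype(np.float32)),
                              Context())
    assert feats.shape[-1] == 32
    assert cfg.n_eeg_tokens == 32


def test_all_zero_input_gives_zero_conv_preactivations():
    """Conv layers carry no bias, so zeros map to zeros before normalization."""
    cfg = small_cfg("eeg")
    model = SeizureTransNet(cfg)
    zeros = Tensor(np.zeros((2, 6, 256), dtype=np.float32))
    h = zeros.reshape(12, 1, 256).conv1d_same(model.cnn.temporal_weight)
    assert np.all(h.data == 0)
    h4 = h.reshape(2, 6, 4, 256).transpose(0, 2, 1, 3).spatial_collapse(
        model.cnn.spatial_weight)
    assert np.all(h4.data == 0)
    assert np.all(h4.depthwise_conv1d_same(model.cnn.dw1).data == 0)


def test_batch_order_equivariance():
    cfg = small_cfg()
    model = SeizureTransNet(cfg)
    x, a = batch(cfg, n=5)
    perm = np.array([3, 0, 4, 1, 2])
    out = model.forward(x, a).data
    out_perm = model.forward(x[perm], a[perm]).data
    np.testing.assert_allclose(out[perm], out_perm, rtol=1e-4, atol=1e-5)


def test_wrong_input_shape_raises():
    cfg = small_cfg("eeg")
    model = SeizureTransNet(cfg)
    with pytest.raises(ValueError, match="expected input"):
        model.forward(np.zeros((2, 5, 256), dtype=np.float32))


# ---------------------------------------------------------------------------
# SK attention
# ---------------------------------------------------------------------------

def test_sk_requires_two_branches():
    with pytest.raises(ValueError, match="at least 2"):
        SKAttention(np.random.default_rng(0), 16, (3,))


def test_sk_identical_branches_fused_unchanged():
    rng = np.random.default_rng(4)
    sk = SKAttention(rng, 8, (3, 5))
    b = Tensor(rng.normal(size=(2, 6, 8)))
    fused = sk.fuse([b, b])
    np.testing.assert_allclose(fused.data, b.data, atol=1e-6)


def test_sk_fusion_is_convex_combination():
    rng = np.random.default_rng(6)
    sk = SKAttention(rng, 8, (3, 5))
    b1 = Tensor(rng.normal(size=(2, 6, 8)))
    b2 = Tensor(rng.normal(size=(2, 6, 8)))
    fused = sk.fuse([b1, b2]).data
    lo = np.minimum(b1.data, b2.data) - 1e-6
    hi = np.maximum(b1.data, b2.data) + 1e-6
    assert ((fused >= lo) & (fused <= hi)).all()


# ---------------------------------------------------------------------------
# encoder block / full forward
# ---------------------------------------------------------------------------

def test_encoder_block_identity_with_zeroed_output_projections():
    cfg = small_cfg()
    model = SeizureTransNet(cfg)
    block = model.blocks[0]
    block.attn.out_proj.weight.data[:] = 0
    block.attn.out_proj.bias.data[:] = 0
    block.sk_out.weight.data[:] = 0
    block.sk_out.bias.data[:] = 0
    rng = np.random.default_rng(0)
    tokens = Tensor(rng.normal(size=(2, 9, cfg.d_model)).astype(np.float32))
    out = block.forward(tokens, Context())
    np.testing.assert_allclose(out.data, tokens.data, atol=1e-6)


def test_forward_shape_and_eval_determinism():
    cfg = small_cfg()
    model = SeizureTransNet(cfg)
    x, a = batch(cfg, n=8)
    s1 = model.forward(x, a).data
    s2 = model.forward(x, a).data
    assert s1.shape == (8, 2)
    np.testing.assert_array_equal(s1, s2)


def test_mode_input_mismatch_errors():
    cfg = small_cfg("eeg+tfpp")
    model = SeizureTransNet(cfg)
    x, a = batch(cfg)
    with pytest.raises(ValueError, match="requires a connectivity"):
        model.forward(x)
    with pytest.raises(ValueError, match="expected connectivity stack"):
        model.forward(x, a[:, :2])
    eeg_model = SeizureTransNet(small_cfg("eeg"))
    with pytest.raises(ValueError, match="takes no connectivity"):
        eeg_model.forward(x, a)


def test_separable_blocks_cheaper_than_dense():
    model = SeizureTransNet(small_cfg("eeg"))
    assert model.cnn.separable_parameter_count() < \
        model.cnn.dense_equivalent_parameter_count()


def test_gradients_reach_every_parameter():
    cfg = small_cfg()
    model = SeizureTransNet(cfg)
    x, a = batch(cfg, n=6, seed=3)
    y = np.array([0, 1, 0, 1, 1, 0])
    model.zero_grad()
    loss = cross_entropy_with_logits(model.forward(x, a), y)
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, f"{name} got no gradient"
        assert np.abs(p.grad).max() > 0, f"{name} gradient identically zero"


def test_seeded_training_is_bit_reproducible(benchmark_arrays):
    from tfppnet.train_eval import train_model

    X, y, A = benchmark_arrays
    idx = np.concatenate([np.flatnonzero(y == 1)[:8], np.flatnonzero(y == 0)[:8]])
    hist = []
    for _ in range(2):
        cfg = reduced_model_config("eeg", seed=5)
        model = SeizureTransNet(cfg)
        h = train_model(model, X[idx], y[idx], max_epochs=3, batch_size=8, seed=5)
        hist.append(h["train_loss"])
    assert hist[0] == hist[1]


def test_untrained_model_near_chance(benchmark_arrays):
    """Seeded random init on 200 balanced segments scores near chance."""
    X, y, A = benchmark_arrays
    idx = np.concatenate([np.flatnonzero(y == 1)[:100], np.flatnonzero(y == 0)[:100]])
    cfg = reduced_model_config("eeg", seed=123)
    model = SeizureTransNet(cfg)
    preds = (model.predict_proba(X[idx])[:, 1] >= 0.5).astype(int)
    acc = float((preds == y[idx]).mean())
    assert 0.3 <= acc <= 0.7


def test_checkpoint_roundtrip(tmp_path):
    cfg = small_cfg()
    model = SeizureTransNet(cfg)
    x, a = batch(cfg, n=3)
    path = tmp_path / "model.npz"
    model.save(path)
    back = SeizureTransNet.load(path)
    assert back.cfg == cfg
    np.testing.assert_array_equal(model.forward(x, a).data,
                                  back.forward(x, a).data)
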