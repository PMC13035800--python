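"""Connectivity estimators against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfppnet import (
    BandSpec, DEFAULT_BANDS, SynthConfig, band_signals, build_tfpp,
    compute_pcc, compute_plv, fuse_pp, generate_record,
    instantaneous_phase, segment,
)
from tfppnet.connectivity import ConnMatrix, mean_offdiagonal

from _oracles import naive_pcc, naive_plv, random_phase_surrogate

FS = 256.0


def tone(freq, dur=4.0, fs=FS, phase=0.0):
    t = np.arange(int(fs * dur)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


# ---------------------------------------------------------------------------
# PCC
# ---------------------------------------------------------------------------

def test_pcc_known_values():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    win = np.stack([x, 2 * x + 3, -x, np.array([2.0, 1.0, 4.0, 3.0])])
    rho = compute_pcc(win).values
    assert rho[0, 1] == pytest.approx(1.0)       # increasing affine map
    assert rho[0, 2] == pytest.approx(-1.0)      # sign flip
    assert rho[0, 3] == pytest.approx(0.6)       # hand-evaluated definition
    np.testing.assert_allclose(np.diag(rho), 1.0)


def test_pcc_zero_variance_channel_rejected():
    win = np.stack([np.ones(32), np.arange(32.0)])
    with pytest.raises(ValueError, match=r"\[0\]"):
        compute_pcc(win)


def test_pcc_affine_invariance():
    rng = np.random.default_rng(5)
    win = rng.normal(size=(4, 256))
    scaled = win * np.array([[2.0], [0.5], [3.0], [1.0]]) + np.array(
        [[1.0], [-2.0], [0.0], [5.0]])
    np.testing.assert_allclose(compute_pcc(win).values,
                               compute_pcc(scaled).values, atol=1e-12)


# ---------------------------------------------------------------------------
# instantaneous phase & PLV
# ---------------------------------------------------------------------------

def test_phase_slope_matches_frequency():
    x = tone(5.0)
    phi = np.unwrap(instantaneous_phase(x))
    n = len(phi)
    core = slice(int(0.1 * n), int(0.9 * n))
    t = np.arange(n)[core] / FS
    slope = np.polyfit(t, phi[core], 1)[0]
    assert abs(slope - 2 * np.pi * 5.0) / (2 * np.pi * 5.0) < 0.01


def test_phase_quadrature_pair_offset():
    t = np.arange(int(FS * 4)) / FS
    pc = instantaneous_phase(np.cos(2 * np.pi * 8 * t))
    ps = instantaneous_phase(np.sin(2 * np.pi * 8 * t))
    n = len(t)
    core = slice(int(0.2 * n), int(0.8 * n))
    diff = np.angle(np.exp(1j * (pc[core] - ps[core])))
    np.testing.assert_allclose(diff, np.pi / 2, atol=1e-2)


def test_phase_negation_shifts_by_pi():
    x = tone(7.0)
    p1, p2 = instantaneous_phase(x), instantaneous_phase(-x)
    core = slice(100, -100)
    diff = np.abs(np.angle(np.exp(1j * (p1[core] - p2[core]))))
    np.testing.assert_allclose(diff, np.pi, atol=1e-6)


def test_phase_error_cases():
    with pytest.raises(ValueError, match="all-zero"):
        instantaneous_phase(np.zeros(64))
    with pytest.raises(ValueError, match="8 samples"):
        instantaneous_phase(np.ones(4))


def test_plv_identical_channels_is_one():
    x = tone(6.0)
    plv = compute_plv(np.stack([x, x]))
    assert plv.values[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_plv_constant_offset_sinusoids():
    win = np.stack([tone(5.0), tone(5.0, phase=np.pi / 3)])
    assert compute_plv(win).values[0, 1] >= 0.99


def test_plv_independent_surrogates_low():
    rng = np.random.default_rng(21)
    win = np.stack([random_phase_surrogate(rng, 1024) for _ in range(2)])
    assert compute_plv(win).values[0, 1] < 0.15


def test_plv_amplitude_scaling_invariance():
    rng = np.random.default_rng(8)
    win = rng.normal(size=(3, 512))
    scaled = win * np.array([[10.0], [0.1], [3.0]])
    np.testing.assert_allclose(compute_plv(win).values,
                               compute_plv(scaled).values, atol=1e-10)


@pytest.mark.parametrize("n_windows", [5])
def test_plv_monotone_in_coupling(n_windows):
    """Mean off-diagonal PLV is non-decreasing in the coupling fraction."""
    means = []
    for coupling in (0.0, 0.25, 0.5, 0.75, 1.0):
        cfg = SynthConfig(n_channels=8, duration=48.0, coupling=coupling,
                          seizure_intervals=[(0.0, 48.0)], seed=17)
        rec = generate_record(cfg)
        vals = [mean_offdiagonal(compute_plv(s.data).values)
                for s in segment(rec, 4.0, 4.0)[:12]]
        means.append(np.mean(vals))
    assert all(b >= a for a, b in zip(means, means[1:]))


def test_vectorized_estimators_match_naive_loops():
    rng = np.random.default_rng(99)
    for _ in range(5):
        win = rng.normal(size=(8, 512))
        np.testing.assert_allclose(compute_pcc(win).values, naive_pcc(win),
                                   atol=1e-10)
        np.testing.assert_allclose(compute_plv(win, edge_trim=0.0).values,
                                   naive_plv(win), atol=1e-10)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def _pair(vals_pcc, vals_plv):
    return (ConnMatrix(vals_pcc, "PCC"), ConnMatrix(vals_plv, "PLV"))


def test_fuse_entrywise_product():
    pcc = np.array([[1.0, -0.8], [-0.8, 1.0]])
    plv = np.array([[1.0, 0.5], [0.5, 1.0]])
    pp = fuse_pp(*_pair(pcc, plv))
    assert pp.kind == "PP"
    assert pp.values[0, 1] == pytest.approx(0.4)


def test_fuse_identity_and_absorbing_elements():
    rng = np.random.default_rng(2)
    raw = rng.uniform(-1, 1, size=(4, 4))
    sym = np.clip((raw + raw.T) / 2, -1, 1)
    np.fill_diagonal(sym, 1.0)
    ones = np.ones((4, 4))
    pp = fuse_pp(*_pair(sym, ones))
    np.testing.assert_allclose(pp.values, np.abs(sym), atol=1e-12)
    zeros = np.eye(4)
    pp0 = fuse_pp(ConnMatrix(zeros, "PCC"), ConnMatrix(ones, "PLV"))
    off = ~np.eye(4, dtype=bool)
    assert (pp0.values[off] == 0).all()


def test_fuse_mismatches_rejected():
    a = ConnMatrix(np.eye(3), "PCC")
    b = ConnMatrix(np.eye(4), "PLV")
    with pytest.raises(ValueError, match="shape"):
        fuse_pp(a, b)
    c = ConnMatrix(np.eye(3), "PLV", window_index=2)
    with pytest.raises(ValueError, match="window/band"):
        fuse_pp(a, c)
    with pytest.raises(ValueError, match="PLV"):
        fuse_pp(a, a)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 31 - 1))
def test_matrix_invariants_on_random_windows(seed):
    """Symmetry, bounds, unit diagonal and the PP <= min(|PCC|, PLV) bound
    hold for estimates from arbitrary random windows."""
    rng = np.random.default_rng(seed)
    win = rng.normal(size=(5, 192)) + 0.3 * rng.normal(size=(1, 192))
    pcc = compute_pcc(win)
    plv = compute_plv(win)
    pp = fuse_pp(pcc, plv)
    for m in (pcc, plv, pp):
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-10)
    assert plv.values.min() >= 0 and plv.values.max() <= 1
    assert pp.values.min() >= 0 and pp.values.max() <= 1
    assert (pp.values <= np.minimum(np.abs(pcc.values), plv.values) + 1e-12).all()


# ---------------------------------------------------------------------------
# band-limited reconstructions
# ---------------------------------------------------------------------------

def _core_rms(x):
    n = x.shape[-1]
    return np.sqrt(np.mean(x[..., n // 10: -n // 10] ** 2))


def test_band_signals_in_band_reconstruction():
    win = np.stack([tone(6.0), tone(6.0, phase=1.0)])
    rec = band_signals(win, DEFAULT_BANDS, fs=FS)
    assert abs(_core_rms(rec["theta"]) / _core_rms(win) - 1) < 0.10
    assert _core_rms(rec["alpha"]) < 0.10 * _core_rms(win)


def test_band_signals_separates_mixture():
    pure6 = tone(6.0)
    mix = pure6 + tone(20.0)
    rec = band_signals(mix[None, :], DEFAULT_BANDS, fs=FS)
    n = len(pure6)
    core = slice(n // 10, -n // 10)
    r = np.corrcoef(rec["theta"][0][core], pure6[core])[0, 1]
    assert r > 0.95


def test_band_signals_empty_band_near_zero():
    win = tone(6.0)[None, :]
    rec = band_signals(win, (BandSpec("gamma", 30.0, 50.0),), fs=FS)
    assert _core_rms(rec["gamma"]) < 0.05 * _core_rms(win)


def test_band_signals_errors():
    win = tone(6.0)[None, :]
    with pytest.raises(ValueError, match="narrow"):
        band_signals(win, (BandSpec("narrow", 5.2, 5.8),), fs=FS)
    with pytest.raises(ValueError, match="Nyquist"):
        band_signals(win, (BandSpec("hi", 100.0, 140.0),), fs=FS)


# ---------------------------------------------------------------------------
# TFPP tensors
# ---------------------------------------------------------------------------

def test_tfpp_counting_and_ordering(ictal_segments):
    t = build_tfpp(ictal_segments[0], n_subwindows=2)
    assert t.values.shape == (2 + len(DEFAULT_BANDS), 18, 18)
    assert t.ordering[:2] == [(0, "broadband"), (1, "broadband")]
    assert [b for _, b in t.ordering[2:]] == [b.name for b in DEFAULT_BANDS]
    t2 = build_tfpp(ictal_segments[1], n_subwindows=2)
    assert t.ordering == t2.ordering


def test_tfpp_slice_invariants(ictal_segments):
    t = build_tfpp(ictal_segments[0])
    for s in t.values:
        np.testing.assert_allclose(s, s.T, atol=1e-10)
        assert s.min() >= 0 and s.max() <= 1 + 1e-12


def test_tfpp_errors(ictal_segments):
    with pytest.raises(ValueError, match="divisible"):
        build_tfpp(ictal_segments[0], n_subwindows=3)
    with pytest.raises(ValueError, match="too short"):
        build_tfpp(ictal_segments[0], n_subwindows=32)


def test_tfpp_ictal_exceeds_interictal(benchmark_tensors):
    """Mean off-diagonal connectivity over all PP slices is clearly higher
    for ictal segments (generator-default contrast, >=20 per class)."""
    def class_mean(label):
        ts = [t for t in benchmark_tensors if t.label == label][:20]
        return np.mean([mean_offdiagonal(s) for t in ts for s in t.values])

    assert class_mean("ictal") - class_mean("interictal") >= 0.15
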