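"""EDF round-trips, filtering oracles, windowing arithmetic, oversampling."""

import numpy as np
import pytest

from tfppnet import (
    CHB_MIT_18, EEGRecord, SynthConfig, bandpass, generate_record, oversample,
    read_edf, segment, write_edf,
)
from tfppnet.eeg_io import (
    EEGSegment, load_segments, normalize_channel_name, save_segments,
)


@pytest.fixture()
def small_record():
    cfg = SynthConfig(n_channels=8, fs=128.0, duration=16.0,
                      seizure_intervals=[(4.0, 10.0)], seed=11)
    return generate_record(cfg)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def test_edf_roundtrip_within_quantization(tmp_path, small_record):
    """write_edf -> mne-backed read_edf preserves fs, names, annotations and
    sample values within the per-channel 16-bit quantization step."""
    path = tmp_path / "rt.edf"
    write_edf(path, small_record)
    back = read_edf(path)
    assert back.fs == small_record.fs
    assert [normalize_channel_name(n) for n in back.channel_names] == \
        [normalize_channel_name(n) for n in small_record.channel_names]
    assert back.seizure_intervals == [(4.0, 10.0)]
    n = small_record.n_samples
    step = (small_record.data.max(axis=1) - small_record.data.min(axis=1)) / 65535
    err = np.abs(back.data[:, :n] - small_record.data)
    assert (err <= step[:, None] + 1e-9).all()


def test_read_edf_subset_order_and_missing_channel(tmp_path, small_record):
    path = tmp_path / "sub.edf"
    write_edf(path, small_record)
    want = [small_record.channel_names[3], small_record.channel_names[0]]
    rec = read_edf(path, want)
    assert rec.n_channels == 2
    np.testing.assert_allclose(rec.data[0], read_edf(path).data[3])
    with pytest.raises(KeyError, match="NOSUCH"):
        read_edf(path, ["NOSUCH"])


def test_chbmit_style_file_default_channel_list(tmp_path):
    """A 23-channel file in CHB-MIT labeling reduces to the packaged 18."""
    extras = ["VNS", "ECG", "LOC-ROC", "EMG-CHIN", "RESP"]
    names = list(CHB_MIT_18) + extras
    rng = np.random.default_rng(0)
    rec = EEGRecord(data=rng.normal(size=(23, 256 * 4)), fs=256.0,
                    channel_names=names, record_id="chbstyle")
    path = tmp_path / "chb.edf"
    write_edf(path, rec)
    out = read_edf(path, CHB_MIT_18)
    assert out.n_channels == 18
    assert [normalize_channel_name(n) for n in out.channel_names] == list(CHB_MIT_18)


def test_channel_name_normalization_variants():
    assert normalize_channel_name(" EEG Fp1-Ref ") == "FP1"
    assert normalize_channel_name("fz-cz") == "FZ-CZ"
    assert normalize_channel_name("EEG  T3") == "T3"


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

def _tone(freq, fs=256.0, dur=8.0, amp=1.0):
    t = np.arange(int(fs * dur)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _record_from(x, fs=256.0):
    return EEGRecord(data=np.stack([x, x]), fs=fs, channel_names=["A", "B"])


def test_bandpass_passband_preserves_amplitude():
    rec = _record_from(_tone(10.0))
    out = bandpass(rec, 1.0, 50.0)
    core = slice(256, -256)  # trim filter transients
    ratio = np.std(out.data[0][core]) / np.std(rec.data[0][core])
    assert abs(ratio - 1.0) < 0.05


def test_bandpass_stopband_attenuates():
    rec = _record_from(_tone(80.0))
    out = bandpass(rec, 1.0, 50.0)
    core = slice(256, -256)  # trim filter transients
    assert np.std(out.data[0][core]) < 0.05 * np.std(rec.data[0][core])


def test_bandpass_removes_dc_offset():
    rec = _record_from(_tone(10.0) + 100.0)
    out = bandpass(rec, 1.0, 50.0)
    assert abs(out.data[0].mean()) < 1.0


def test_bandpass_rejects_bad_bands():
    rec = _record_from(_tone(10.0))
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(rec, 1.0, 128.0)
    with pytest.raises(ValueError):
        bandpass(rec, 50.0, 1.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_segment_count_and_labels():
    rng = np.random.default_rng(1)
    rec = EEGRecord(data=rng.normal(size=(2, 256 * 60)), fs=256.0,
                    channel_names=["A", "B"], seizure_intervals=[(10.0, 20.0)])
    segs = segment(rec, window_s=4.0, stride_s=4.0, ictal_overlap_frac=0.5)
    assert len(segs) == 15
    by_start = {s.start_s: s.label for s in segs}
    for start in (8.0, 12.0, 16.0):
        assert by_start[start] == "ictal"
    assert by_start[20.0] == "interictal"
    assert by_start[0.0] == "interictal"


def test_segment_too_short_record_returns_empty(caplog):
    rec = EEGRecord(data=np.zeros((2, 256 * 3)), fs=256.0, channel_names=["A", "B"])
    with caplog.at_level("WARNING"):
        assert segment(rec, window_s=4.0) == []
    assert "shorter" in caplog.text


@pytest.mark.parametrize("duration,stride", [
    (d, s) for d in (8, 11, 16, 23, 40, 60) for s in (1.0, 2.0, 3.5, 4.0)
])
def test_segment_count_closed_form(duration, stride):
    rec = EEGRecord(data=np.zeros((1, int(256 * duration))), fs=256.0,
                    channel_names=["A"])
    segs = segment(rec, window_s=4.0, stride_s=stride)
    assert len(segs) == int(np.floor((duration - 4.0) / stride)) + 1


def test_segment_dense_ictal_grid_adds_only_ictal_windows():
    rec = EEGRecord(data=np.zeros((1, 256 * 40)) + np.random.default_rng(0).normal(size=(1, 256 * 40)),
                    fs=256.0, channel_names=["A"], seizure_intervals=[(10.0, 20.0)])
    base = segment(rec, 4.0, 4.0)
    dense = segment(rec, 4.0, 4.0, ictal_stride_s=1.0)
    added = [s for s in dense if s.start_s not in {b.start_s for b in base}]
    assert added and all(s.label == "ictal" for s in added)


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------

def _seg(label, value, n=64):
    return EEGSegment(data=np.full((2, n), float(value)), label=label,
                      start_s=float(value), fs=16.0)


def test_oversample_balances_and_keeps_originals():
    segs = [_seg("interictal", i) for i in range(10)] + [_seg("ictal", 100 + i)
                                                         for i in range(2)]
    out = oversample(segs, seed=0)
    assert len(out) == 20
    labels = [s.label for s in out]
    assert labels.count("ictal") == labels.count("interictal") == 10
    # all originals retained
    starts = sorted({s.start_s for s in out if s.label == "ictal"})
    assert starts == [100.0, 101.0]


def test_oversample_never_fabricates_values():
    segs = [_seg("interictal", i) for i in range(7)] + [_seg("ictal", 50)]
    out = oversample(segs, seed=3)
    originals = {s.data.tobytes() for s in segs}
    assert all(s.data.tobytes() in originals for s in out)


def test_oversample_deterministic_and_balanced_passthrough():
    segs = [_seg("interictal", i) for i in range(4)] + [_seg("ictal", 10 + i)
                                                        for i in range(4)]
    a = oversample(segs, seed=9)
    b = oversample(segs, seed=9)
    assert [s.start_s for s in a] == [s.start_s for s in b]
    assert sorted(s.start_s for s in a) == sorted(s.start_s for s in segs)


def test_oversample_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        oversample([_seg("ictal", 1), _seg("ictal", 2)], seed=0)


def test_segment_archive_roundtrip(tmp_path, small_record):
    segs = segment(small_record, 4.0, 4.0)
    path = tmp_path / "segs.npz"
    save_segments(path, segs)
    back = load_segments(path)
    assert len(back) == len(segs)
    assert [s.label for s in back] == [s.label for s in segs]
    np.testing.assert_allclose(back[0].data, segs[0].data, atol=1e-4)
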