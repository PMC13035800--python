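"""Shared fixtures: synthetic recordings, labeled segments, and the
benchmark dataset (about 200 segments per class with connectivity tensors)
used by the model-level and end-to-end checks."""

import numpy as np
import pytest

from tfppnet import (
    ModelConfig, SynthConfig, bandpass, build_tfpp_dataset, generate_record,
    segment,
)


@pytest.fixture(scope="session")
def long_record():
    """One 18-channel recording, first half ictal, second half background."""
    cfg = SynthConfig(duration=168.0, seizure_intervals=[(0.0, 84.0)], seed=3)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def labeled_segments(long_record):
    return segment(long_record, window_s=4.0, stride_s=4.0)


@pytest.fixture(scope="session")
def ictal_segments(labeled_segments):
    return [s for s in labeled_segments if s.label == "ictal"]


@pytest.fixture(scope="session")
def interictal_segments(labeled_segments):
    return [s for s in labeled_segments if s.label == "interictal"]


def _make_benchmark(n_per_class=200, n_records=10, seed0=100):
    """Generator-default recordings -> band-passed 4-s segments, 200/class."""
    ictal, inter = [], []
    for i in range(n_records):
        cfg = SynthConfig(duration=168.0, seizure_intervals=[(0.0, 84.0)],
                          seed=seed0 + i)
        rec = generate_record(cfg)
        rec.record_id = f"bench{i:02d}"
        segs = segment(bandpass(rec, 1.0, 50.0), window_s=4.0, stride_s=4.0)
        ictal.extend(s for s in segs if s.label == "ictal")
        inter.extend(s for s in segs if s.label == "interictal")
    return ictal[:n_per_class] + inter[:n_per_class]


@pytest.fixture(scope="session")
def benchmark_segments():
    return _make_benchmark()


@pytest.fixture(scope="session")
def benchmark_tensors(benchmark_segments):
    return build_tfpp_dataset(benchmark_segments)


@pytest.fixture(scope="session")
def benchmark_arrays(benchmark_segments, benchmark_tensors):
    X = np.stack([s.data for s in benchmark_segments]).astype(np.float32)
    y = np.array([s.y for s in benchmark_segments])
    A = np.stack([t.values for t in benchmark_tensors]).astype(np.float32)
    return X, y, A


def reduced_model_config(input_mode: str, seed: int = 0,
                         n_tfpp_slices: int = 7) -> ModelConfig:
    """Small-but-complete model used for training runs in the suite."""
    return ModelConfig(
        input_mode=input_mode, n_channels=18, samples_per_segment=1024,
        n_tfpp_slices=n_tfpp_slices if input_mode != "eeg" else 0,
        n_temporal_filters=4, depth_multiplier=2, d_model=32, n_heads=4,
        n_encoder_layers=1, seed=seed)
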