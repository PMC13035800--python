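"""Validated run configuration: one YAML file drives every pipeline stage.

Unknown keys are rejected (typos fail loudly), all defaults are
materialized on load, and a loaded config re-serializes to an equivalent
file. CLI flags override config values.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .connectivity import DEFAULT_BANDS, BandSpec
from .model import INPUT_MODES

__all__ = ["RunConfig", "load_config", "DEMO_CONFIG"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SynthSection(_Section):
    """Synthetic-recording parameters (see synthetic_eeg.SynthConfig)."""
    n_channels: int = 18
    fs: float = 256.0
    duration: float = 120.0
    coupling: float = 0.8
    drive_freq: float = 3.0
    phase_jitter: float = 0.1
    noise_std: float = 1.0
    interictal_coupling: float = 0.1
    n_records: int = 2
    seizure_intervals: List[Tuple[float, float]] = Field(
        default_factory=lambda: [(40.0, 80.0)])


class PreprocessSection(_Section):
    lo_hz: float = 1.0
    hi_hz: float = 50.0
    window_s: float = 4.0
    stride_s: float = 4.0
    ictal_stride_s: Optional[float] = 1.0
    ictal_overlap_frac: float = 0.5
    channels: Optional[List[str]] = None   # None: all channels, file order


class TFPPSection(_Section):
    bands: List[Tuple[str, float, float]] = Field(
        default_factory=lambda: [(b.name, b.lo_hz, b.hi_hz) for b in DEFAULT_BANDS])
    n_subwindows: int = 2

    def band_specs(self):
        return tuple(BandSpec(n, lo, hi) for n, lo, hi in self.bands)


class ModelSection(_Section):
    input_mode: str = "eeg+tfpp"
    temporal_kernel_len: int = 64
    n_temporal_filters: int = 8
    depth_multiplier: int = 2
    sep_kernel_len: int = 15
    pool_sizes: Tuple[int, int] = (4, 8)
    dropout_cnn: float = 0.25
    d_model: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    sk_kernel_sizes: Tuple[int, ...] = (3, 5)
    dropout_head: float = 0.5

    @field_validator("input_mode")
    @classmethod
    def _check_mode(cls, v):
        if v not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}, got {v!r}")
        return v


class TrainingSection(_Section):
    k: int = 10
    seed: int = 0
    lr: float = 0.001
    batch_size: int = 256
    max_epochs: int = 50
    patience: int = 10
    val_fraction: float = 0.1


class RunConfig(_Section):
    """Top-level configuration with one section per pipeline stage."""
    synth: SynthSection = Field(default_factory=SynthSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    tfpp: TFPPSection = Field(default_factory=TFPPSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_config(path=None) -> RunConfig:
    """Load a YAML config, or the defaults when no path is given."""
    return RunConfig() if path is None else RunConfig.from_yaml(path)


#: Small fast end-to-end configuration used by `tfppnet demo` and smoke tests.
DEMO_CONFIG = RunConfig.model_validate({
    "synth": {"n_channels": 8, "fs": 128.0, "duration": 120.0, "n_records": 2,
              "seizure_intervals": [(40.0, 80.0)]},
    "preprocess": {"hi_hz": 45.0, "ictal_stride_s": 2.0},
    "tfpp": {"bands": [("delta", 1.0, 4.0), ("theta", 4.0, 8.0),
                       ("alpha", 8.0, 13.0), ("beta", 13.0, 30.0)],
             "n_subwindows": 2},
    "model": {"temporal_kernel_len": 32, "n_temporal_filters": 4,
              "depth_multiplier": 2, "d_model": 32, "n_heads": 4,
              "n_encoder_layers": 1, "pool_sizes": (4, 8)},
    "training": {"k": 2, "batch_size": 64, "max_epochs": 3, "patience": 10},
})
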