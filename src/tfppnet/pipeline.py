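"""End-to-end pipeline: simulate/ingest -> preprocess -> TFPP -> train -> evaluate.

Stages run in the framework order; every stage writes its artifacts under
the run directory, and a failure aborts with the stage name and cause.
Given a seed the whole run is reproducible on one device.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .config import RunConfig
from .connectivity import build_tfpp_dataset, save_tfpp_dataset
from .eeg_io import bandpass, read_edf, save_segments, segment, write_edf
from .model import ModelConfig
from .synthetic_eeg import SynthConfig, generate_record
from .train_eval import SeizureDetector

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline", "simulate_records",
           "preprocess_record", "model_config_from_run"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def simulate_records(cfg: RunConfig, seed: int):
    """Generate `n_records` synthetic recordings (seeds seed, seed+1, ...)."""
    s = cfg.synth
    records = []
    for i in range(s.n_records):
        sc = SynthConfig(
            n_channels=s.n_channels, fs=s.fs, duration=s.duration,
            coupling=s.coupling, drive_freq=s.drive_freq,
            phase_jitter=s.phase_jitter, noise_std=s.noise_std,
            interictal_coupling=s.interictal_coupling,
            seizure_intervals=[tuple(iv) for iv in s.seizure_intervals],
            seed=seed + i)
        rec = generate_record(sc)
        rec.record_id = f"syn{i:02d}"
        records.append(rec)
    return records


def preprocess_record(record, cfg: RunConfig):
    """Band-pass filter and segment one record per the config."""
    p = cfg.preprocess
    filtered = bandpass(record, p.lo_hz, p.hi_hz)
    return segment(filtered, window_s=p.window_s, stride_s=p.stride_s,
                   ictal_overlap_frac=p.ictal_overlap_frac,
                   ictal_stride_s=p.ictal_stride_s)


def model_config_from_run(cfg: RunConfig, n_channels: int, samples_per_segment: int,
                          n_tfpp_slices: int, seed: int) -> ModelConfig:
    m = cfg.model
    return ModelConfig(
        input_mode=m.input_mode, n_channels=n_channels,
        samples_per_segment=samples_per_segment, n_tfpp_slices=n_tfpp_slices,
        temporal_kernel_len=m.temporal_kernel_len,
        n_temporal_filters=m.n_temporal_filters,
        depth_multiplier=m.depth_multiplier, sep_kernel_len=m.sep_kernel_len,
        pool_sizes=tuple(m.pool_sizes), dropout_cnn=m.dropout_cnn,
        d_model=m.d_model, n_heads=m.n_heads,
        n_encoder_layers=m.n_encoder_layers,
        sk_kernel_sizes=tuple(m.sk_kernel_sizes),
        dropout_head=m.dropout_head, seed=seed)


def run_pipeline(cfg: RunConfig, out_dir, seed: int | None = None,
                 edf_paths=None, write_edfs: bool = True):
    """Run all stages; returns the CVResults of the final evaluation.

    With `edf_paths` the simulate stage is replaced by ingestion of those
    EDF files (annotations from their sidecars); otherwise synthetic
    recordings are generated from the config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.training.seed if seed is None else seed

    stage = "simulate" if edf_paths is None else "ingest"
    try:
        if edf_paths is None:
            records = simulate_records(cfg, seed)
            if write_edfs:
                rec_dir = out_dir / "records"
                rec_dir.mkdir(exist_ok=True)
                for rec in records:
                    write_edf(rec_dir / f"{rec.record_id}.edf", rec)
        else:
            records = [read_edf(p, cfg.preprocess.channels) for p in edf_paths]
        logger.info("[%s] %d record(s)", stage, len(records))
    except Exception as e:
        raise PipelineError(stage, e) from e

    try:
        segments = []
        for rec in records:
            segments.extend(preprocess_record(rec, cfg))
        if not segments:
            raise ValueError("preprocessing produced no segments")
        save_segments(out_dir / "segments.npz", segments)
        n_ictal = sum(s.y for s in segments)
        logger.info("[preprocess] %d segments (%d ictal / %d interictal)",
                    len(segments), n_ictal, len(segments) - n_ictal)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("preprocess", e) from e

    mode = cfg.model.input_mode
    tensors = None
    try:
        if mode != "eeg":
            kind = {"eeg+tfpp": "PP", "eeg+pcc": "absPCC", "eeg+plv": "PLV"}[mode]
            tensors = build_tfpp_dataset(segments, bands=cfg.tfpp.band_specs(),
                                         n_subwindows=cfg.tfpp.n_subwindows, kind=kind)
            save_tfpp_dataset(out_dir / "tfpp.npz", tensors)
            logger.info("[build-tfpp] %d tensors of %d slices (kind=%s)",
                        len(tensors), tensors[0].n_slices, kind)
    except Exception as e:
        raise PipelineError("build-tfpp", e) from e

    try:
        n_slices = 0 if tensors is None else tensors[0].n_slices
        mc = model_config_from_run(cfg, segments[0].data.shape[0],
                                   segments[0].data.shape[1], n_slices, seed)
        detector = SeizureDetector(segments, tfpp=tensors, model_config=mc)
        t = cfg.training
        results = detector.fit(k=t.k, seed=seed, lr=t.lr, batch_size=t.batch_size,
                               max_epochs=t.max_epochs, patience=t.patience,
                               val_fraction=t.val_fraction)
    except Exception as e:
        raise PipelineError("train", e) from e

    try:
        results.to_csv(out_dir / "metrics.csv")
        (out_dir / "summary.txt").write_text(results.summary() + "\n")
        with open(out_dir / "details.json", "w") as fh:
            json.dump({"seed": seed, "config": cfg.model_dump(mode="json"),
                       "folds": [{k2: v for k2, v in d.items() if k2 != "scores"}
                                 for d in results.details]}, fh, indent=1)
        logger.info("[evaluate] avg acc=%.3f auc=%s", results.acc,
                    "n/a" if results.auc is None else f"{results.auc:.3f}")
    except Exception as e:
        raise PipelineError("evaluate", e) from e
    return results
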