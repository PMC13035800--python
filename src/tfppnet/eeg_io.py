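"""EEG record I/O, filtering, windowing and class rebalancing.

Recordings travel as :class:`EEGRecord` (channels x samples, microvolt-like
units) with seizure annotations as half-open ``[start_s, end_s)`` intervals.
EDF files are read through :mod:`mne`; a minimal EDF+ 16-bit writer is
implemented here so the synthetic generator can emit files any EDF reader
accepts. Seizure annotations live in a plain-text sidecar
``<record>.seizures.txt`` with one ``start_s<TAB>end_s`` line per seizure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecord", "EEGSegment", "read_edf", "write_edf", "bandpass", "segment",
    "oversample", "read_seizure_sidecar", "write_seizure_sidecar",
    "save_segments", "load_segments", "CHB_MIT_18", "SIENA_29",
]

# Default channel lists. 18 bipolar 10-20 derivations in the CHB-MIT
# convention and 29 referential 10-20 electrodes in the Siena convention;
# both overridable wherever a channel subset is accepted.
CHB_MIT_18 = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
]
SIENA_29 = [
    "FP1", "F3", "C3", "P3", "O1", "F7", "T3", "T5",
    "FC1", "FC5", "CP1", "CP5", "F9",
    "FZ", "CZ", "PZ",
    "FP2", "F4", "C4", "P4", "O2", "F8", "T4", "T6",
    "FC2", "FC6", "CP2", "CP6", "F10",
]


@dataclass
class EEGRecord:
    """A continuous multichannel recording.

    data: (n_channels, n_samples) array in microvolt-like units.
    seizure_intervals: half-open [start_s, end_s) intervals in seconds.
    """

    data: np.ndarray
    fs: float
    channel_names: list
    seizure_intervals: list = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        dur = self.duration
        for lo, hi in self.seizure_intervals:
            if not (0 <= lo < hi <= dur + 1e-9):
                raise ValueError(
                    f"seizure interval ({lo}, {hi}) outside recording [0, {dur:.3f}]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EEGSegment:
    """One fixed-length labeled window cut from a record."""

    data: np.ndarray
    label: str                 # "ictal" or "interictal"
    start_s: float
    record_id: str = ""
    fs: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.label not in ("ictal", "interictal"):
            raise ValueError(f"label must be 'ictal' or 'interictal', got {self.label!r}")

    @property
    def y(self) -> int:
        """Integer label: ictal=1 (positive class), interictal=0."""
        return 1 if self.label == "ictal" else 0


# ---------------------------------------------------------------------------
# channel-name normalization and EDF I/O
# ---------------------------------------------------------------------------

_REF_SUFFIX = re.compile(r"[- ](REF|LE|AVG)$", re.IGNORECASE)


def normalize_channel_name(name: str) -> str:
    """Case-insensitive canonical form: strip whitespace, an 'EEG ' prefix,
    and a reference suffix like '-Ref'."""
    s = name.strip().upper()
    if s.startswith("EEG "):
        s = s[4:].strip()
    s = _REF_SUFFIX.sub("", s)
    return re.sub(r"\s+", " ", s)


def read_seizure_sidecar(edf_path) -> list:
    """Read `start_s<TAB>end_s` lines from <record>.seizures.txt if present."""
    edf_path = Path(edf_path)
    sidecar = edf_path.parent / (edf_path.stem + ".seizures.txt")
    if not sidecar.exists():
        return []
    intervals = []
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", " ").split()
        if len(parts) != 2:
            raise ValueError(f"malformed line in {sidecar}: {line!r}")
        intervals.append((float(parts[0]), float(parts[1])))
    return intervals


def write_seizure_sidecar(edf_path, intervals) -> Path:
    edf_path = Path(edf_path)
    sidecar = edf_path.parent / (edf_path.stem + ".seizures.txt")
    lines = [f"{float(lo):.6g}\t{float(hi):.6g}" for lo, hi in intervals]
    sidecar.write_text("\n".join(lines) + ("\n" if lines else ""))
    return sidecar


def read_edf(path, channel_subset=None) -> EEGRecord:
    """Read an EDF file, optionally restricted to `channel_subset` in order.

    Channel matching is case-insensitive after whitespace / 'EEG ' prefix /
    reference-suffix normalization. Seizure intervals are loaded from the
    plain-text sidecar when present. Data are returned in microvolts.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    data = raw.get_data() * 1e6  # volts -> microvolts
    if channel_subset is not None:
        norm_map = {}
        for i, nm in enumerate(names):
            norm_map.setdefault(normalize_channel_name(nm), i)
        rows, kept_names = [], []
        missing = []
        for want in channel_subset:
            key = normalize_channel_name(want)
            if key not in norm_map:
                missing.append(want)
            else:
                rows.append(norm_map[key])
                kept_names.append(names[norm_map[key]])
        if missing:
            raise KeyError(
                f"channels {missing} not found in {path.name}; available: {names}")
        data = data[rows]
        names = kept_names
    intervals = read_seizure_sidecar(path)
    return EEGRecord(data=data, fs=float(raw.info["sfreq"]), channel_names=names,
                     seizure_intervals=intervals, record_id=path.stem)


def write_edf(path, record: EEGRecord, sidecar: bool = True) -> Path:
    """Write a 16-bit EDF file (1-second data records) plus annotation sidecar.

    The tail is zero-padded to a whole number of records; values are scaled
    per channel to the full digital range, so quantization error is
    (phys_max - phys_min) / 2^16 per channel.
    """
    path = Path(path)
    fs = record.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    nchan = record.n_channels
    n_records = int(np.ceil(record.n_samples / spr))
    padded = np.zeros((nchan, n_records * spr))
    padded[:, :record.n_samples] = record.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin <= 0
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    def f(text, width):
        b = str(text)[:width].encode("ascii", "replace")
        return b + b" " * (width - len(b))

    header = b"".join([
        f("0", 8),
        f(record.record_id or "X", 80),
        f("Startdate 01-JAN-2000 " + (record.record_id or "X"), 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 * (1 + nchan), 8),
        f("", 44),
        f(n_records, 8),
        f("1", 8),
        f(nchan, 4),
    ])
    fields = [
        ("%s", [f(nm, 16) for nm in record.channel_names]),
        ("transducer", [f("", 80)] * nchan),
        ("dim", [f("uV", 8)] * nchan),
        ("pmin", [f(np.format_float_positional(v, precision=6, trim="-")[:8], 8) for v in pmin]),
        ("pmax", [f(np.format_float_positional(v, precision=6, trim="-")[:8], 8) for v in pmax]),
        ("dmin", [f(dmin, 8)] * nchan),
        ("dmax", [f(dmax, 8)] * nchan),
        ("prefilter", [f("", 80)] * nchan),
        ("spr", [f(spr, 8)] * nchan),
        ("reserved", [f("", 32)] * nchan),
    ]
    sig_header = b"".join(b"".join(col) for _, col in fields)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    if sidecar and record.seizure_intervals:
        write_seizure_sidecar(path, record.seizure_intervals)
    return path


# ---------------------------------------------------------------------------
# filtering, segmentation, oversampling
# ---------------------------------------------------------------------------

def bandpass(record: EEGRecord, lo_hz: float = 1.0, hi_hz: float = 50.0,
             order: int = 4) -> EEGRecord:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    The clinical default (1-50 Hz) removes drift and mains/high-frequency
    content while keeping delta through gamma.
    """
    if not 0 < lo_hz < hi_hz:
        raise ValueError(f"need 0 < lo_hz < hi_hz, got ({lo_hz}, {hi_hz})")
    if hi_hz >= record.fs / 2:
        raise ValueError(
            f"hi_hz={hi_hz} must be below the Nyquist frequency {record.fs / 2}")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=record.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, record.data, axis=-1)
    return EEGRecord(data=filtered, fs=record.fs,
                     channel_names=list(record.channel_names),
                     seizure_intervals=list(record.seizure_intervals),
                     record_id=record.record_id)


def _overlap_with_intervals(start: float, end: float, intervals) -> float:
    return sum(max(0.0, min(end, hi) - max(start, lo)) for lo, hi in intervals)


def segment(record: EEGRecord, window_s: float = 4.0, stride_s: float | None = None,
            ictal_overlap_frac: float = 0.5,
            ictal_stride_s: float | None = None) -> list:
    """Cut a record into fixed-length labeled windows.

    Windows start at 0 and step by ``stride_s`` (default: non-overlapping).
    A window is ictal iff its overlap with any seizure interval is at least
    ``ictal_overlap_frac * window_s``. When ``ictal_stride_s`` is given, an
    additional finer grid is scanned and its *ictal* windows are added
    (duplicate starts dropped) — an oversampling-friendly densification of
    the scarce class.
    """
    stride_s = window_s if stride_s is None else stride_s
    if stride_s <= 0:
        raise ValueError(f"stride_s must be positive, got {stride_s}")
    win = int(round(window_s * record.fs))
    if win > record.n_samples:
        logger.warning("record %s shorter (%.2fs) than window (%.2fs); no segments",
                       record.record_id, record.duration, window_s)
        return []

    def cut(stride, keep_interictal):
        segs = []
        n_windows = int(np.floor((record.duration - window_s) / stride)) + 1
        for w in range(n_windows):
            start = w * stride
            i0 = int(round(start * record.fs))
            if i0 + win > record.n_samples:
                break
            ov = _overlap_with_intervals(start, start + window_s,
                                         record.seizure_intervals)
            label = "ictal" if ov >= ictal_overlap_frac * window_s - 1e-12 else "interictal"
            if label == "interictal" and not keep_interictal:
                continue
            segs.append(EEGSegment(data=record.data[:, i0:i0 + win].copy(),
                                   label=label, start_s=start,
                                   record_id=record.record_id, fs=record.fs))
        return segs

    segments = cut(stride_s, keep_interictal=True)
    if ictal_stride_s is not None:
        have = {round(s.start_s, 9) for s in segments}
        for s in cut(ictal_stride_s, keep_interictal=False):
            if round(s.start_s, 9) not in have:
                segments.append(s)
                have.add(round(s.start_s, 9))
        segments.sort(key=lambda s: s.start_s)
    return segments


def oversample(segments, seed: int = 0) -> list:
    """Balance classes by duplicating minority segments with replacement.

    All originals are retained; no new signal values are synthesized. The
    result is shuffled deterministically by ``seed``.
    """
    ictal = [s for s in segments if s.label == "ictal"]
    inter = [s for s in segments if s.label == "interictal"]
    if not ictal or not inter:
        raise ValueError("oversample needs both classes present "
                         f"(ictal={len(ictal)}, interictal={len(inter)})")
    rng = np.random.default_rng(seed)
    minority, majority = (ictal, inter) if len(ictal) < len(inter) else (inter, ictal)
    out = list(segments)
    deficit = len(majority) - len(minority)
    if deficit > 0:
        picks = rng.integers(0, len(minority), size=deficit)
        out.extend(minority[i] for i in picks)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


# ---------------------------------------------------------------------------
# segment archives (documented npz container)
# ---------------------------------------------------------------------------

def save_segments(path, segments) -> Path:
    """Write segments to an .npz archive: data (N,C,T), labels, starts,
    record ids, fs."""
    if not segments:
        raise ValueError("no segments to save")
    path = Path(path)
    data = np.stack([s.data for s in segments]).astype(np.float32)
    np.savez_compressed(
        path,
        data=data,
        labels=np.array([s.label for s in segments]),
        starts=np.array([s.start_s for s in segments]),
        record_ids=np.array([s.record_id for s in segments]),
        fs=np.array([segments[0].fs]),
    )
    return path


def load_segments(path) -> list:
    z = np.load(Path(path), allow_pickle=False)
    fs = float(z["fs"][0])
    return [EEGSegment(data=z["data"][i].astype(np.float64), label=str(z["labels"][i]),
                       start_s=float(z["starts"][i]), record_id=str(z["record_ids"][i]),
                       fs=fs)
            for i in range(z["data"].shape[0])]
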