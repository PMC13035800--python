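"""Functional brain network construction: PCC, PLV, PP fusion, TFPP tensors.

Two complementary connectivity estimators are computed per channel pair:

* **PCC** — the Pearson correlation coefficient between the two amplitude
  time series, measuring linear amplitude synchrony:

      rho_xy = sum_i (x_i - xbar)(y_i - ybar)
               / sqrt( sum_i (x_i - xbar)^2  *  sum_i (y_i - ybar)^2 )

* **PLV** — the phase-locking value, the modulus of the time-averaged unit
  phasor of the instantaneous phase difference (phases from the analytic
  signal via the Hilbert transform):

      PLV_xy = | (1/N) sum_t exp( j (phi_x(t) - phi_y(t)) ) |

The two are fused entrywise (Hadamard product) into the phase-correlation
matrix ``PP = |PCC| o PLV``, which is high only where amplitude coupling
and phase locking coincide. PP matrices over broadband time sub-windows and
over STFT-band-limited reconstructions of the full segment are stacked, in
a fixed documented order, into the time-frequency PP (TFPP) tensor that the
classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandSpec", "ConnMatrix", "TFPPTensor", "DEFAULT_BANDS",
    "compute_pcc", "compute_plv", "instantaneous_phase", "fuse_pp",
    "band_signals", "build_tfpp", "build_tfpp_dataset",
    "save_tfpp_dataset", "load_tfpp_dataset", "mean_offdiagonal",
]

#: fraction of samples discarded at each end of a window before averaging
#: the phase difference (Hilbert edge transients)
PHASE_EDGE_TRIM = 0.10

VALID_KINDS = ("PCC", "absPCC", "PLV", "PP")


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [lo_hz, hi_hz)."""
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not 0 <= self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: need 0 <= lo < hi, got "
                             f"({self.lo_hz}, {self.hi_hz})")


#: Clinically standard EEG rhythm bands (Hz), configurable everywhere.
DEFAULT_BANDS = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 50.0),
)


@dataclass
class ConnMatrix:
    """A square symmetric channel x channel connectivity matrix."""

    values: np.ndarray
    kind: str
    window_index: int = 0
    band: object = "broadband"   # BandSpec or the string "broadband"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        c = self.values.shape[0]
        if self.values.shape != (c, c):
            raise ValueError(f"connectivity matrix must be square, got {self.values.shape}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix not symmetric within 1e-10")
        if self.kind == "PCC":
            if self.values.min() < -1 - 1e-10 or self.values.max() > 1 + 1e-10:
                raise ValueError("PCC entries must lie in [-1, 1]")
        else:
            if self.values.min() < -1e-10 or self.values.max() > 1 + 1e-10:
                raise ValueError(f"{self.kind} entries must lie in [0, 1]")
        if self.kind in ("PCC", "absPCC", "PLV"):
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
                raise ValueError(f"{self.kind} diagonal must be 1")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def band_name(self) -> str:
        return self.band.name if isinstance(self.band, BandSpec) else str(self.band)


@dataclass
class TFPPTensor:
    """Ordered stack of PP matrices over time sub-windows x frequency bands.

    ``ordering`` lists one ``(window_index, band_name)`` pair per slice;
    time sub-windows come first (broadband), then whole-segment bands in
    configuration order. The ordering must be identical for every segment
    of a dataset.
    """

    values: np.ndarray                  # (S, C, C)
    ordering: list                      # [(window_index, band_name), ...]
    record_id: str = ""
    start_s: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(f"TFPP tensor must be (S, C, C), got {self.values.shape}")
        if len(self.ordering) != self.values.shape[0]:
            raise ValueError(
                f"ordering length {len(self.ordering)} != number of slices "
                f"{self.values.shape[0]}")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_window(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if hasattr(x, "data") and not isinstance(x, np.ndarray):
        arr = np.asarray(x.data, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected (channels, samples), got shape {arr.shape}")
    return arr


def compute_pcc(window, window_index: int = 0, band="broadband") -> ConnMatrix:
    """Pearson correlation matrix of a (channels x samples) window.

    Fails fast on zero-variance channels (the correlation denominator
    vanishes) rather than emitting NaN networks.
    """
    x = _as_window(window)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples for a correlation")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance channel(s) {dead.tolist()}: "
                         "Pearson correlation undefined")
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T
    denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
    rho = cov / denom
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return ConnMatrix(values=rho, kind="PCC", window_index=window_index, band=band)


def instantaneous_phase(signal_1d) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) of the analytic signal."""
    x = np.asarray(signal_1d, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if x.size < 8:
        raise ValueError("need at least 8 samples for a usable phase estimate")
    if not np.any(x != 0):
        raise ValueError("all-zero signal: instantaneous phase undefined")
    return np.angle(sps.hilbert(x))


def compute_plv(window, window_index: int = 0, band="broadband",
                edge_trim: float = PHASE_EDGE_TRIM) -> ConnMatrix:
    """Phase-locking value matrix of a (channels x samples) window.

    Phases come from the Hilbert analytic signal; a fraction ``edge_trim``
    of samples at each end is discarded before averaging the unit phasors,
    since the analytic signal is unreliable at window edges.
    """
    x = _as_window(window)
    n = x.shape[1]
    if n < 8:
        raise ValueError("need at least 8 samples for PLV")
    dead = np.flatnonzero(~np.any(x != 0, axis=1))
    if dead.size:
        raise ValueError(f"all-zero channel(s) {dead.tolist()}: phase undefined")
    analytic = sps.hilbert(x, axis=1)
    phase = np.angle(analytic)
    k = int(np.floor(edge_trim * n))
    core = phase[:, k:n - k] if k > 0 else phase
    phasors = np.exp(1j * core)
    # PLV(a,b) = |mean_t e^{j(phi_a - phi_b)}| = |(1/N) sum phasor_a conj(phasor_b)|
    plv = np.abs(phasors @ np.conj(phasors.T)) / core.shape[1]
    plv = np.clip((plv + plv.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(plv, 1.0)
    return ConnMatrix(values=plv, kind="PLV", window_index=window_index, band=band)


def fuse_pp(pcc: ConnMatrix, plv: ConnMatrix) -> ConnMatrix:
    """Hadamard fusion PP = |PCC| o PLV.

    Taking |PCC| keeps anti-correlated pairs from cancelling; the entrywise
    product then assigns weight only where amplitude coupling and phase
    locking agree, so PP(a,b) <= min(|PCC(a,b)|, PLV(a,b)).
    """
    if pcc.kind not in ("PCC", "absPCC"):
        raise ValueError(f"first argument must be a PCC/absPCC matrix, got {pcc.kind}")
    if plv.kind != "PLV":
        raise ValueError(f"second argument must be a PLV matrix, got {plv.kind}")
    if pcc.values.shape != plv.values.shape:
        raise ValueError(f"shape mismatch: {pcc.values.shape} vs {plv.values.shape}")
    if pcc.window_index != plv.window_index or pcc.band_name != plv.band_name:
        raise ValueError(
            f"window/band mismatch: PCC (w={pcc.window_index}, band={pcc.band_name}) "
            f"vs PLV (w={plv.window_index}, band={plv.band_name})")
    pp = np.abs(pcc.values) * plv.values
    return ConnMatrix(values=np.clip(pp, 0.0, 1.0), kind="PP",
                      window_index=pcc.window_index, band=pcc.band)


# ---------------------------------------------------------------------------
# band-limited reconstructions and the TFPP tensor
# ---------------------------------------------------------------------------

def band_signals(window, bands, fs: float, stft_window_s: float = 1.0,
                 stft_overlap: float = 0.5) -> dict:
    """Band-limited time-domain reconstructions via STFT masking.

    For each band, the STFT (Hann taper, ``stft_window_s`` windows,
    ``stft_overlap`` fractional overlap) is computed per channel, bins
    outside ``[lo_hz, hi_hz)`` are zeroed, and the inverse STFT reconstructs
    a signal of the original length. The connectivity estimators then apply
    to each band unchanged.
    """
    x = _as_window(window)
    nperseg = int(round(stft_window_s * fs))
    nperseg = min(nperseg, x.shape[1])
    noverlap = int(round(stft_overlap * nperseg))
    freqs, _, z = sps.stft(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, boundary="zeros", padded=True)
    out = {}
    for band in bands:
        if band.hi_hz > fs / 2:
            raise ValueError(f"band {band.name} ({band.lo_hz}-{band.hi_hz} Hz) "
                             f"exceeds the Nyquist frequency {fs / 2}")
        mask = (freqs >= band.lo_hz) & (freqs < band.hi_hz)
        if not mask.any():
            raise ValueError(
                f"band {band.name} ({band.lo_hz}-{band.hi_hz} Hz) covers no STFT "
                f"bin at fs={fs}, nperseg={nperseg}")
        zb = np.where(mask[None, :, None], z, 0.0)
        _, rec = sps.istft(zb, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, boundary=True)
        out[band.name] = rec[:, :x.shape[1]]
    return out


MIN_SUBWINDOW_SAMPLES = 64


def build_tfpp(seg, bands=DEFAULT_BANDS, n_subwindows: int = 2,
               kind: str = "PP", fs: float | None = None) -> TFPPTensor:
    """Assemble the time-frequency connectivity tensor for one segment.

    Slices, in fixed order: first ``n_subwindows`` broadband equal time
    sub-windows, then one whole-segment slice per band (configuration
    order), each a matrix of the requested ``kind`` ("PP", "absPCC" or
    "PLV" — the latter two feed the single-network ablations).
    """
    if kind not in ("PP", "absPCC", "PLV"):
        raise ValueError(f"kind must be PP, absPCC or PLV, got {kind!r}")
    data = seg.data if hasattr(seg, "data") else np.asarray(seg)
    fs = fs if fs is not None else getattr(seg, "fs", None)
    if not fs:
        raise ValueError("sampling rate unknown: pass fs= or a segment with .fs")
    c, t = data.shape
    if t % n_subwindows != 0:
        raise ValueError(f"segment length {t} not divisible into {n_subwindows} "
                         "equal sub-windows")
    sub = t // n_subwindows
    if sub < MIN_SUBWINDOW_SAMPLES:
        raise ValueError(f"sub-windows of {sub} samples are too short for "
                         f"connectivity estimation (min {MIN_SUBWINDOW_SAMPLES})")

    def one_matrix(win, idx, band):
        if kind == "PLV":
            return compute_plv(win, window_index=idx, band=band).values
        pcc = compute_pcc(win, window_index=idx, band=band)
        if kind == "absPCC":
            return np.abs(pcc.values)
        plv = compute_plv(win, window_index=idx, band=band)
        return fuse_pp(pcc, plv).values

    slices, ordering = [], []
    for w in range(n_subwindows):
        win = data[:, w * sub:(w + 1) * sub]
        slices.append(one_matrix(win, w, "broadband"))
        ordering.append((w, "broadband"))
    per_band = band_signals(data, bands, fs=fs)
    for band in bands:
        slices.append(one_matrix(per_band[band.name], n_subwindows, band))
        ordering.append((n_subwindows, band.name))

    return TFPPTensor(values=np.stack(slices), ordering=ordering,
                      record_id=getattr(seg, "record_id", ""),
                      start_s=getattr(seg, "start_s", 0.0),
                      label=getattr(seg, "label", ""))


def build_tfpp_dataset(segments, bands=DEFAULT_BANDS, n_subwindows: int = 2,
                       kind: str = "PP") -> list:
    """Build TFPP tensors for a list of segments, enforcing one ordering."""
    tensors = [build_tfpp(s, bands=bands, n_subwindows=n_subwindows, kind=kind)
               for s in segments]
    if tensors:
        ref = tensors[0].ordering
        for t in tensors[1:]:
            if t.ordering != ref:
                raise RuntimeError("inconsistent TFPP slice ordering across segments")
    return tensors


def mean_offdiagonal(matrix: np.ndarray) -> float:
    """Mean of the off-diagonal entries — the global connectivity summary
    used to contrast ictal and interictal networks."""
    m = np.asarray(matrix)
    c = m.shape[0]
    if c < 2:
        raise ValueError("need at least 2 channels")
    mask = ~np.eye(c, dtype=bool)
    return float(m[mask].mean())


def save_tfpp_dataset(path, tensors) -> None:
    """Write TFPP tensors to .npz: values (N,S,C,C), ordering, metadata."""
    if not tensors:
        raise ValueError("no tensors to save")
    ordering = tensors[0].ordering
    np.savez_compressed(
        path,
        values=np.stack([t.values for t in tensors]).astype(np.float32),
        order_windows=np.array([w for w, _ in ordering]),
        order_bands=np.array([b for _, b in ordering]),
        labels=np.array([t.label for t in tensors]),
        starts=np.array([t.start_s for t in tensors]),
        record_ids=np.array([t.record_id for t in tensors]),
    )


def load_tfpp_dataset(path) -> list:
    z = np.load(path, allow_pickle=False)
    ordering = [(int(w), str(b)) for w, b in zip(z["order_windows"], z["order_bands"])]
    return [TFPPTensor(values=z["values"][i].astype(np.float64), ordering=list(ordering),
                       record_id=str(z["record_ids"][i]), start_s=float(z["starts"][i]),
                       label=str(z["labels"][i]))
            for i in range(z["values"].shape[0])]
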