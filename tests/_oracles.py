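"""Independent brute-force oracles: literal per-pair evaluations of the
correlation and phase-locking definitions, kept deliberately naive."""

import numpy as np
from scipy.signal import hilbert


def naive_pcc(window: np.ndarray) -> np.ndarray:
    """Pearson correlation, literal per-pair double loop."""
    c, n = window.shape
    out = np.empty((c, c))
    for a in range(c):
        for b in range(c):
            x, y = window[a], window[b]
            xm, ym = x.mean(), y.mean()
            num = np.sum((x - xm) * (y - ym))
            den = np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2))
            out[a, b] = num / den
    return out


def naive_plv(window: np.ndarray) -> np.ndarray:
    """Phase-locking value, literal per-pair loop over the full window."""
    c, n = window.shape
    phases = [np.angle(hilbert(window[ch])) for ch in range(c)]
    out = np.empty((c, c))
    for a in range(c):
        for b in range(c):
            diff = phases[a] - phases[b]
            out[a, b] = np.abs(np.mean(np.exp(1j * diff)))
    return out


def random_phase_surrogate(rng: np.random.Generator, n: int) -> np.ndarray:
    """A signal with the spectrum of white noise but fully randomized phases
    (independent surrogates have no phase relationship by construction)."""
    amp = np.ones(n // 2 + 1)
    phase = rng.uniform(0, 2 * np.pi, size=n // 2 + 1)
    spec = amp * np.exp(1j * phase)
    spec[0] = 0
    return np.fft.irfft(spec, n=n)
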