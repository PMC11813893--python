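"""TF24: the 24-parameter time/frequency statistical feature bank.

Eleven time-domain descriptors (p1-p11: mean, std, square-root amplitude, RMS,
peak, skewness, kurtosis, and the crest / clearance / shape / impulse factors)
and thirteen spectral descriptors (p12-p24: moments of the one-sided periodogram
and frequency-weighted shape statistics such as the centroid and RMS frequency).
This hand-crafted representation is the classical baseline the learned
autoencoder features are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TF24_NAMES = tuple(f"p{i}" for i in range(1, 25))


class DegenerateWindowError(ValueError):
    """Raised when a window's statistics are undefined (constant signal,
    empty or single-line spectrum)."""


@dataclass(frozen=True)
class SpectrumRep:
    """One-sided power spectrum: frequency per bin (Hz) and power per bin."""

    f: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=np.float64)
        s = np.asarray(self.s, dtype=np.float64)
        if f.shape != s.shape or f.ndim != 1:
            raise ValueError("f and s must be 1-D arrays of equal length")
        if np.any(s < 0):
            raise ValueError("power must be nonnegative")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "s", s)

    @property
    def K(self) -> int:
        return self.f.size


def time_features(x: np.ndarray) -> np.ndarray:
    """p1..p11 of an amplitude vector.

    p1 mean; p2 sample std (N-1); p3 square-root amplitude (mean sqrt|x|)^2;
    p4 RMS; p5 peak = max|x|; p6 skewness and p7 kurtosis (N-1 normalization,
    non-excess); p8 crest p5/p4; p9 clearance p5/p3; p10 shape p4/mean|x|;
    p11 impulse p5/mean|x|.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.max(x) == np.min(x):
        raise DegenerateWindowError("degenerate window: constant signal")
    p1 = x.mean()
    d = x - p1
    p2 = np.sqrt(np.sum(d**2) / (n - 1))
    p3 = (np.mean(np.sqrt(np.abs(x)))) ** 2
    p4 = np.sqrt(np.mean(x**2))
    p5 = np.max(np.abs(x))
    if p2 == 0.0 or p4 == 0.0:
        raise DegenerateWindowError("degenerate window: constant signal")
    p6 = np.sum(d**3) / ((n - 1) * p2**3)
    p7 = np.sum(d**4) / ((n - 1) * p2**4)
    mean_abs = np.mean(np.abs(x))
    p8 = p5 / p4
    p9 = p5 / p3
    p10 = p4 / mean_abs
    p11 = p5 / mean_abs
    return np.array([p1, p2, p3, p4, p5, p6, p7, p8, p9, p10, p11])


def power_spectrum(x: np.ndarray, fs: float) -> SpectrumRep:
    """One-sided periodogram: ``s_k = |DFT(x)_k|^2 / N`` over bins 0..N//2."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    spec = np.fft.rfft(x)
    s = (np.abs(spec) ** 2) / n
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumRep(f=f, s=s)


def freq_features(spec: SpectrumRep) -> np.ndarray:
    """p12..p24 of a one-sided power spectrum.

    Raw moments of the bin powers (p12-p15), the power-weighted frequency
    centroid p16 and spread p17, RMS frequency p18, and the higher
    frequency-weighted shape ratios p19-p24.
    """
    f, s, K = spec.f, spec.s, spec.K
    total = np.sum(s)
    if total <= 0:
        raise DegenerateWindowError("degenerate window: all-zero spectrum")
    p12 = total / K
    ds = s - p12
    p13 = np.sum(ds**2) / (K - 1)
    if p13 > 0:
        p14 = np.sum(ds**3) / (K * p13**1.5)
        p15 = np.sum(ds**4) / (K * p13**2)
    else:
        p14 = p15 = 0.0  # flat spectrum: power skewness/kurtosis vanish by convention
    p16 = np.sum(f * s) / total
    df = f - p16
    p17 = np.sqrt(np.sum(df**2 * s) / K)
    p18 = np.sqrt(np.sum(f**2 * s) / total)
    sf2 = np.sum(f**2 * s)
    sf4 = np.sum(f**4 * s)
    p19 = np.sqrt(sf4 / sf2)
    p20 = sf2 / np.sqrt(total * sf4)
    if p17 == 0.0:
        raise DegenerateWindowError(
            "degenerate window: single spectral line (p21-p24 undefined)"
        )
    p21 = p17 / p16
    p22 = np.sum(df**3 * s) / (K * p17**3)
    p23 = np.sum(df**4 * s) / (K * p17**4)
    p24 = np.sum(np.sqrt(np.abs(df)) * s) / (K * np.sqrt(p17))
    return np.array(
        [p12, p13, p14, p15, p16, p17, p18, p19, p20, p21, p22, p23, p24]
    )


def tf24(x: np.ndarray, fs: float) -> np.ndarray:
    """The full 24-vector ``[time_features(x), freq_features(periodogram)]``."""
    return np.concatenate([time_features(x), freq_features(power_spectrum(x, fs))])
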