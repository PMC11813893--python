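"""Synthetic phonocardiogram generator.

Clinical heart-sound recordings are rarely shareable, so the package ships a
generator that emulates the statistical structure the detection pipeline relies
on: quasi-periodic cardiac cycles, two Gaussian-enveloped tone bursts per cycle
(the first and second heart sounds, S1 and S2), an optional band-limited
noise-like murmur occupying the systolic S1->S2 interval (the anomaly class),
and additive Gaussian ambient noise with a controllable standard deviation.

The defaults are deliberately conservative: S1/S2 fundamentals near 50 Hz and a
murmur band of 25-60 Hz keep all diagnostic energy inside the 0-62.5 Hz
approximation band that a 5-level wavelet decomposition at 4 kHz retains, so the
denoising stage removes noise rather than the anomaly itself.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .audio import AudioSignal, normalize


@dataclass(frozen=True)
class PCGSpec:
    """Parameters of one synthetic phonocardiogram record.

    Attributes
    ----------
    duration_s : float
        Record length in seconds; must cover at least one cardiac cycle.
    sample_rate : int
        Sampling frequency in Hz.
    heart_rate_bpm : float
        Beats per minute; one S1+S2 pair per beat.
    s1_freq, s2_freq : float
        Fundamental frequencies (Hz) of the S1 and S2 tone bursts.
    s2_offset_frac : float
        Fraction of the cycle between S1 onset and S2 onset (systole length).
    murmur_present : bool
        Whether a murmur occupies every S1->S2 interval.
    murmur_band : tuple[float, float]
        Murmur pass band (lo, hi) in Hz; must sit below Nyquist.
    murmur_rel_amplitude : float
        Ratio of murmur RMS to the S1 peak amplitude (before normalization).
    cycle_jitter_frac : float
        Std of per-cycle timing jitter, as a fraction of the cycle period.
    burst_std_s : float
        Std (seconds) of the Gaussian envelope of each S1/S2 burst.
    seed : int
        Seed for the record's private random stream.
    """

    duration_s: float = 10.0
    sample_rate: int = 4000
    heart_rate_bpm: float = 70.0
    s1_freq: float = 50.0
    s2_freq: float = 45.0
    s2_offset_frac: float = 0.35
    murmur_present: bool = False
    murmur_band: tuple[float, float] = (25.0, 60.0)
    murmur_rel_amplitude: float = 0.8
    cycle_jitter_frac: float = 0.0
    burst_std_s: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.murmur_band
        nyq = self.sample_rate / 2.0
        if not (0 < lo < hi < nyq):
            raise ValueError(
                f"murmur_band must satisfy 0 < lo < hi < {nyq} Hz, got {self.murmur_band}"
            )
        if self.murmur_rel_amplitude < 0:
            raise ValueError("murmur_rel_amplitude must be >= 0")
        if not (0 < self.s2_offset_frac < 1):
            raise ValueError("s2_offset_frac must lie in (0, 1)")
        if self.duration_s * self.heart_rate_bpm < 60.0:
            raise ValueError("duration shorter than one cardiac cycle")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["murmur_band"] = list(self.murmur_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PCGSpec":
        d = dict(d)
        if "murmur_band" in d:
            d["murmur_band"] = tuple(d["murmur_band"])
        return cls(**d)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian ambient-noise parameters (std in normalized units)."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _gaussian_burst(t: np.ndarray, center: float, freq: float, std: float) -> np.ndarray:
    env = np.exp(-0.5 * ((t - center) / std) ** 2)
    return env * np.sin(2.0 * np.pi * freq * (t - center))


def murmur_intervals(spec: PCGSpec) -> list[tuple[float, float]]:
    """The systolic (S1 onset -> S2 onset) intervals that carry the murmur.

    Empty when ``murmur_present`` is false. Computed from the nominal
    (jitter-free) cycle grid; jitter only perturbs the bursts, so the nominal
    grid is the label of record for windowing.
    """
    if not spec.murmur_present or spec.murmur_rel_amplitude == 0:
        return []
    period = 60.0 / spec.heart_rate_bpm
    n_cycles = int(np.floor(spec.duration_s / period))
    out = []
    for c in range(n_cycles):
        start = c * period
        out.append((start, start + spec.s2_offset_frac * period))
    return out


def synthesize_unnormalized(spec: PCGSpec) -> AudioSignal:
    """The physical-scale waveform before peak normalization (S1 peak = 1).

    At this scale murmur energy adds on top of the heart sounds, so
    band-energy comparisons between matched records are meaningful;
    :func:`generate_pcg` rescales the whole record to unit peak, which
    shrinks the heart sounds whenever the murmur sets the peak.
    """
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    period = 60.0 / spec.heart_rate_bpm
    n_cycles = int(np.floor(spec.duration_s / period))

    jitter_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    x = np.zeros(n)
    s1_amp = 1.0
    s2_amp = 0.8
    for c in range(n_cycles):
        base = c * period
        jit = (
            jitter_rng.normal(0.0, spec.cycle_jitter_frac * period)
            if spec.cycle_jitter_frac > 0
            else 0.0
        )
        s1_center = base + jit + 2 * spec.burst_std_s
        s2_center = base + jit + spec.s2_offset_frac * period + 2 * spec.burst_std_s
        x += s1_amp * _gaussian_burst(t, s1_center, spec.s1_freq, spec.burst_std_s)
        x += s2_amp * _gaussian_burst(t, s2_center, spec.s2_freq, spec.burst_std_s)

    if spec.murmur_present and spec.murmur_rel_amplitude > 0:
        murmur_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
        white = murmur_rng.standard_normal(n)
        sos = sps.butter(4, spec.murmur_band, btype="bandpass", fs=spec.sample_rate, output="sos")
        band = sps.sosfiltfilt(sos, white)
        for start, stop in murmur_intervals(spec):
            i0, i1 = int(round(start * spec.sample_rate)), int(round(stop * spec.sample_rate))
            i1 = min(i1, n)
            seg = band[i0:i1]
            rms = np.sqrt(np.mean(seg**2))
            if rms > 0:
                # taper the segment edges (10 ms) to avoid clicks
                win = np.ones(i1 - i0)
                ramp = min(int(0.010 * spec.sample_rate), (i1 - i0) // 2)
                if ramp > 0:
                    edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
                    win[:ramp] = edge
                    win[-ramp:] = edge[::-1]
                x[i0:i1] += spec.murmur_rel_amplitude * s1_amp / rms * seg * win

    return AudioSignal(x, spec.sample_rate)


def generate_pcg(spec: PCGSpec) -> AudioSignal:
    """Generate one synthetic phonocardiogram record.

    One S1 and one S2 Gaussian-enveloped tone burst per cardiac cycle; when
    ``murmur_present`` with positive relative amplitude, band-limited Gaussian
    noise fills every S1->S2 interval at ``murmur_rel_amplitude`` times the S1
    peak (RMS). The output is peak-normalized to [-1, 1]. Identical specs
    (including the seed) produce bitwise-identical output.
    """
    return normalize(synthesize_unnormalized(spec))


def add_gaussian_noise(signal: AudioSignal, noise: NoiseSpec) -> AudioSignal:
    """Add i.i.d. Gaussian noise of std ``noise.sigma`` (seeded, reproducible).

    The output is deliberately NOT re-normalized: the noise calibration is in
    the input's units, and re-scaling would silently change the noise level the
    robustness study sweeps over.
    """
    if noise.sigma == 0.0:
        return AudioSignal(signal.samples.copy(), signal.sample_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(noise.seed), 2]))
    e = rng.normal(0.0, noise.sigma, signal.samples.size)
    return AudioSignal(signal.samples + e, signal.sample_rate)
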