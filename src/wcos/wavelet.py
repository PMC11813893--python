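"""Wavelet-reconstruction (WR) denoising.

The denoiser performs a multilevel decimated discrete wavelet decomposition,
zeroes every detail band, and resynthesises from the deepest approximation
alone. With an orthogonal wavelet this is a linear projection onto the
low-frequency approximation subspace: at depth L it retains roughly the
0 .. fs/2^(L+1) band (62.5 Hz for the sym4/5-level default at 4 kHz), which
covers the fundamental heart sounds while discarding wideband noise.

Unlike threshold denoising, no data-dependent shrinkage is applied: all detail
coefficients are discarded unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .audio import AudioSignal


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family, decomposition depth and boundary-extension mode."""

    family: str = "sym4"
    levels: int = 5
    extension_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        try:
            w = pywt.Wavelet(self.family)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet family {self.family!r}") from exc
        if not w.orthogonal:
            raise ValueError(f"wavelet {self.family!r} is not orthogonal")

    @property
    def wavelet(self) -> "pywt.Wavelet":
        return pywt.Wavelet(self.family)


@dataclass
class WaveletCoeffs:
    """Coefficients of a multilevel decomposition.

    ``details[0]`` is the finest (level-1) detail band; ``approx`` is the
    deepest approximation. ``original_length`` records the source sample count
    so synthesis can crop back exactly (the decimated transform is not
    length-preserving).
    """

    approx: np.ndarray
    details: list[np.ndarray]
    original_length: int

    @property
    def levels(self) -> int:
        return len(self.details)


def decompose(signal: AudioSignal, spec: WaveletSpec = WaveletSpec()) -> WaveletCoeffs:
    """Decimated filter-bank decomposition to ``spec.levels`` depth.

    Raises
    ------
    ValueError
        If the signal is too short for the requested depth; the message names
        the maximum feasible depth.
    """
    w = spec.wavelet
    max_level = pywt.dwt_max_level(len(signal), w.dec_len)
    if spec.levels > max_level:
        raise ValueError(
            f"signal of {len(signal)} samples supports at most {max_level} "
            f"decomposition levels with {spec.family} (requested {spec.levels})"
        )
    coeffs = pywt.wavedec(signal.samples, w, mode=spec.extension_mode, level=spec.levels)
    approx, details_deep_first = coeffs[0], coeffs[1:]
    return WaveletCoeffs(
        approx=approx,
        details=list(reversed(details_deep_first)),  # store finest first
        original_length=len(signal),
    )


def zero_details(coeffs: WaveletCoeffs) -> WaveletCoeffs:
    """Replace every detail band with zeros; the approximation is untouched."""
    return WaveletCoeffs(
        approx=coeffs.approx.copy(),
        details=[np.zeros_like(d) for d in coeffs.details],
        original_length=coeffs.original_length,
    )


def reconstruct(
    coeffs: WaveletCoeffs, spec: WaveletSpec = WaveletSpec(), sample_rate: int = 4000
) -> AudioSignal:
    """Inverse filter-bank synthesis, cropped/padded to ``original_length``."""
    if len(coeffs.details) != spec.levels:
        raise ValueError(
            f"coefficient depth {len(coeffs.details)} does not match spec.levels {spec.levels}"
        )
    clist = [coeffs.approx] + list(reversed(coeffs.details))
    try:
        x = pywt.waverec(clist, spec.wavelet, mode=spec.extension_mode)
    except ValueError as exc:
        raise ValueError(f"mismatched coefficient lengths: {exc}") from exc
    n = coeffs.original_length
    if x.size > n:
        x = x[:n]
    elif x.size < n:
        x = np.pad(x, (0, n - x.size))
    return AudioSignal(x, sample_rate)


def denoise(signal: AudioSignal, spec: WaveletSpec = WaveletSpec()) -> AudioSignal:
    """Wavelet-reconstruction denoising: decompose, zero details, resynthesise.

    Same length and sample rate as the input. Linear in the input, hence
    homogeneous: ``denoise(a*x) == a*denoise(x)``.
    """
    coeffs = zero_details(decompose(signal, spec))
    return reconstruct(coeffs, spec, sample_rate=signal.sample_rate)
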