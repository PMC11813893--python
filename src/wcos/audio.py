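"""Mono audio container and PCM WAV I/O.

The package operates on amplitude-normalized mono waveforms; :class:`AudioSignal`
is the container every stage (denoising, windowing, feature extraction) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile


class DegenerateSignalError(ValueError):
    """Raised when an operation is undefined on an all-zero / constant signal."""


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform.

    Parameters
    ----------
    samples
        Real amplitudes, nominally in [-1, 1] after :func:`normalize`.
    sample_rate
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"expected a mono (1-D) signal, got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate


def normalize(signal: AudioSignal) -> AudioSignal:
    """Peak-normalize so that ``max |x| == 1``.

    Raises
    ------
    DegenerateSignalError
        If the signal is identically zero.
    """
    peak = np.max(np.abs(signal.samples))
    if peak == 0.0:
        raise DegenerateSignalError("degenerate signal: all samples are zero")
    return AudioSignal(signal.samples / peak, signal.sample_rate)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM mono WAV.

    Samples are clipped to [-1, 1] and quantized to int16; the round trip
    through :func:`read_wav` is exact to within one quantization step (2^-15).
    """
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), signal.sample_rate, pcm)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono PCM WAV file into an :class:`AudioSignal`.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        For multi-channel files or unsupported encodings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"expected a mono WAV file, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.float32 or data.dtype == np.float64:
        samples = data.astype(np.float64)
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    return AudioSignal(samples, int(rate))
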