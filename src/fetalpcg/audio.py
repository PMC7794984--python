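"""Audio container and WAV I/O.

The :class:`AudioSegment` is the currency of the whole pipeline: a mono,
double-precision sample array with its sampling rate.  Files are plain
PCM 16-bit mono WAV read and written through :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioSegment", "read_wav", "write_wav"]

_PCM16_FULL_SCALE = 32767.0


@dataclass(frozen=True)
class AudioSegment:
    """A mono sampled signal.

    Parameters
    ----------
    samples : ndarray of float64
        Normalized amplitudes, nominally in [-1, 1].  Values must be finite.
    sampling_rate : float
        Samples per second, > 0.
    """

    samples: np.ndarray = field(repr=False)
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate


def read_wav(path) -> AudioSegment:
    """Read a mono PCM or float WAV file into an :class:`AudioSegment`.

    Integer PCM is rescaled to [-1, 1] (16-bit full scale maps to +/-1);
    float data is taken as already normalized.  Multi-channel files are
    rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data / _PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    samples = np.clip(samples, -1.0, 1.0)
    return AudioSegment(samples=samples, sampling_rate=float(rate))


def write_wav(segment: AudioSegment, path) -> None:
    """Write an :class:`AudioSegment` as PCM 16-bit mono WAV.

    Samples outside [-1, 1] are clipped with a warning.
    """
    x = segment.samples
    if np.any(np.abs(x) > 1.0):
        warnings.warn("samples outside [-1, 1] clipped on WAV write", stacklevel=2)
        x = np.clip(x, -1.0, 1.0)
    pcm = np.round(x * _PCM16_FULL_SCALE).astype(np.int16)
    wavfile.write(path, int(segment.sampling_rate), pcm)
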