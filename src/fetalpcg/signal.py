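"""Pretreatment: float conversion, zero-mean, normalization, decimation,
and windowing utilities.

The acquisition chain delivers PCM integers; everything downstream works on
double-precision, mean-removed, max-abs-normalized samples in [-1, 1] (the
epsilon-tube width and retrain threshold of the SVR denoiser are only
meaningful on a bounded amplitude scale).  Rate extraction runs at 1 kHz,
so the 8 kHz input is decimated by an integer factor after zero-phase
anti-alias filtering.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .audio import AudioSegment

__all__ = ["preprocess", "decimate", "segment"]


def preprocess(raw) -> AudioSegment | np.ndarray:
    """Convert to float64, remove the mean, normalize by max-abs to [-1, 1].

    Accepts a raw sample sequence (returns an ndarray) or an
    :class:`AudioSegment` (returns a new AudioSegment at the same rate).
    A constant input maps to all-zeros; this is documented behaviour, not
    an error.  Idempotent up to floating tolerance.
    """
    if isinstance(raw, AudioSegment):
        return AudioSegment(preprocess(raw.samples), raw.sampling_rate)
    x = np.asarray(raw, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot preprocess an empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    x = x - x.mean()
    m = np.max(np.abs(x))
    if m > 0:
        x = x / m
    return x


def decimate(seg: AudioSegment, target_rate: float) -> AudioSegment:
    """Downsample by an integer factor with zero-phase anti-alias filtering.

    The low-pass cutoff sits at 0.8x the target Nyquist; filtering is
    forward-backward (zero phase) so peak times are not shifted.  Only
    integer decimation factors are supported (e.g. 8 kHz -> 1 kHz).
    """
    factor_f = seg.sampling_rate / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target rate {target_rate} must divide sampling rate "
            f"{seg.sampling_rate} (got factor {factor_f})"
        )
    n_out = len(seg) // factor
    if factor == 1:
        return AudioSegment(seg.samples[:n_out].copy(), float(target_rate))
    b, a = butter(8, 0.8 / factor)
    filtered = filtfilt(b, a, seg.samples)
    return AudioSegment(filtered[: n_out * factor : factor], float(target_rate))


def segment(sig: AudioSegment, window_s: float, hop_s: float) -> list[AudioSegment]:
    """Slice into half-open windows [t, t+w) advanced by `hop_s`.

    Yields floor((T - w)/hop) + 1 windows; a trailing partial window is
    discarded.  A window longer than the signal is an error.
    """
    if window_s <= 0 or hop_s <= 0:
        raise ValueError("window_s and hop_s must be > 0")
    fs = sig.sampling_rate
    wn = int(round(window_s * fs))
    hn = int(round(hop_s * fs))
    if wn > len(sig):
        raise ValueError(
            f"window of {window_s} s exceeds signal duration {sig.duration:.3f} s"
        )
    starts = range(0, len(sig) - wn + 1, hn)
    return [AudioSegment(sig.samples[s : s + wn].copy(), fs) for s in starts]
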