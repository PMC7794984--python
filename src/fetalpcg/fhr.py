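"""Fetal heart rate extraction.

The recording is scanned with a sliding window (default 4 s, hop 1 s) at a
1 kHz working rate.  Inside each window, S1 peaks are detected on a
smoothed energy envelope, and the peak-to-peak intervals pass through an
interval-consensus step: intervals are sorted largest-to-smallest into P,
adjacent differences form E, and pairs of mutually similar intervals are
greedily admitted into a selected set H starting from the smallest
difference.  Intervals distorted by a missed or spurious beat sit far from
the rest and are never admitted, so the mean interval A = mean(H) — and
the window rate f_t = 60/A — is robust to detection errors.  Between
windows the raw rates are smoothed with an exponentially weighted moving
average v_t = beta*v_{t-1} + (1-beta)*f_t started at v_0 = 0, whose
cold-start bias is removed by dividing by 1 - beta^t; the corrected output
F_t is a convex combination of the raw rates seen so far.

Two textbook baselines are included for comparison: the direct method
(plain mean of all intervals in the window) and beat counting, whose rate
resolution is quantized at 60/window seconds bpm (15 bpm for 4 s windows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .audio import AudioSegment
from .signal import decimate

__all__ = [
    "WindowConfig",
    "PeakList",
    "IntervalConsensus",
    "FHRSeries",
    "InsufficientPeaksError",
    "detect_peaks",
    "consensus_interval",
    "rate_from_interval",
    "ewma_bias_corrected",
    "extract_fhr",
    "rate_direct",
    "rate_by_counting",
    "counting_resolution_bpm",
    "influence_decay",
]

logger = logging.getLogger("fetalpcg.fhr")


class InsufficientPeaksError(ValueError):
    """Fewer than 3 peaks in the window: no interval consensus possible."""


@dataclass(frozen=True)
class WindowConfig:
    """Windowing and peak-detection settings.

    The refractory period caps the detectable rate (0.25 s -> 240 bpm) and
    suppresses the quieter S2 sound that follows S1 within the systolic
    interval; the envelope threshold rejects sub-dominant activity.
    """

    window_s: float = 4.0
    hop_s: float = 1.0
    downsample_to: float = 1000.0
    refractory_s: float = 0.25
    envelope_smooth_ms: float = 20.0
    peak_threshold_frac: float = 0.3
    consensus_tolerance_s: float = 0.05
    consensus_mode: str = "tolerance"  # or "literal"

    def __post_init__(self) -> None:
        if not self.window_s > self.hop_s > 0:
            raise ValueError("need window_s > hop_s > 0")
        if self.consensus_mode not in ("tolerance", "literal"):
            raise ValueError(
                f"consensus_mode must be 'tolerance' or 'literal', "
                f"got {self.consensus_mode!r}"
            )
        if not 0 < self.peak_threshold_frac < 1:
            raise ValueError("peak_threshold_frac must be in (0, 1)")


@dataclass(frozen=True)
class PeakList:
    """Detected peaks: strictly ascending times and envelope amplitudes."""

    times: np.ndarray = field(repr=False)
    amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        a = np.asarray(self.amplitudes, dtype=np.float64)
        if t.size != a.size:
            raise ValueError("times and amplitudes must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly ascending")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class IntervalConsensus:
    """Per-window consensus matrices.

    P: intervals sorted largest-to-smallest; E: adjacent differences of P;
    H: the selected (mutually similar) intervals; A: mean of H, seconds.
    """

    P: np.ndarray
    E: np.ndarray
    H: np.ndarray
    A: float
    tolerance: float


@dataclass
class FHRSeries:
    """Per-window raw rates f and bias-corrected smoothed rates F."""

    f: np.ndarray
    F: np.ndarray
    beta: float
    v_raw: np.ndarray
    window_starts: Optional[np.ndarray] = None
    flagged: Optional[np.ndarray] = None     # windows without consensus
    n_peaks: Optional[np.ndarray] = None
    consensus_size: Optional[np.ndarray] = None


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(int(width), 1)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_peaks(seg: AudioSegment, config: WindowConfig = WindowConfig()) -> PeakList:
    """Detect dominant (S1) bursts in a window.

    The detection statistic is the squared signal smoothed by a short
    moving average (an energy envelope); local maxima above
    `peak_threshold_frac` of the envelope maximum and separated by at
    least the refractory period are peaks.  An empty PeakList is a valid
    result.
    """
    fs = seg.sampling_rate
    env = _moving_average(seg.samples ** 2,
                          round(config.envelope_smooth_ms / 1000.0 * fs))
    peak = env.max() if env.size else 0.0
    if peak <= 0:
        return PeakList(np.empty(0), np.empty(0))
    distance = max(int(round(config.refractory_s * fs)), 1)
    idx, _props = find_peaks(env, height=config.peak_threshold_frac * peak,
                             distance=distance)
    return PeakList(idx / fs, env[idx])


def consensus_interval(peaks: PeakList,
                       config: WindowConfig = WindowConfig()) -> IntervalConsensus:
    """Select mutually similar peak intervals and average them.

    With m peaks, the m-1 intervals are sorted descending into P and the
    m-2 adjacent differences form E.  Repeatedly the index i of the
    smallest remaining difference is taken, E(i) is retired, and P(i),
    P(i+1) join H (each P entry at most once).  In tolerance mode the loop
    stops once the smallest remaining difference exceeds the tolerance, so
    outlying intervals (missed or spurious beats) are excluded; literal
    mode runs until every difference is retired, which admits every
    interval.  A is the mean of H; H may be empty in tolerance mode when
    no two intervals agree.
    """
    m = len(peaks)
    if m < 3:
        raise InsufficientPeaksError(
            f"need >= 3 peaks for interval consensus, got {m}"
        )
    intervals = np.diff(peaks.times)
    P = np.sort(intervals)[::-1]
    E = P[:-1] - P[1:]
    work = E.astype(np.float64).copy()
    selected: set[int] = set()
    while np.any(np.isfinite(work)):
        i = int(np.nanargmin(np.where(np.isfinite(work), work, np.nan)))
        if config.consensus_mode == "tolerance" and work[i] > config.consensus_tolerance_s:
            break
        work[i] = np.inf
        selected.add(i)
        selected.add(i + 1)
    H = P[sorted(selected)]
    A = float(np.mean(H)) if H.size else math.nan
    return IntervalConsensus(P=P, E=E, H=H, A=A,
                             tolerance=config.consensus_tolerance_s)


def rate_from_interval(A: float) -> float:
    """Beats per minute from a mean beat interval in seconds: 60/A."""
    if not A > 0:
        raise ValueError(f"mean interval must be > 0 s, got {A}")
    return 60.0 / A


def ewma_bias_corrected(f, beta: float, mode: str = "corrected") -> FHRSeries:
    """Exponentially weighted moving average with cold-start bias correction.

    Maintains v_t = beta*v_{t-1} + (1-beta)*f_t from v_0 = 0 and emits
    F_t = v_t / (1 - beta^t), t starting at 1.  The correction exactly
    reproduces a constant input and keeps F_t inside [min, max] of the raw
    rates seen so far.  `mode="literal"` instead applies the division
    inside the recursion (the corrected value feeds back), kept for
    comparison.
    """
    if not 0 < beta < 1:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    if mode not in ("corrected", "literal"):
        raise ValueError(f"mode must be 'corrected' or 'literal', got {mode!r}")
    f = np.asarray(f, dtype=np.float64)
    if f.size == 0:
        raise ValueError("raw rate series is empty")
    v_raw = np.empty(f.size)
    F = np.empty(f.size)
    v = 0.0
    for t in range(1, f.size + 1):
        v = beta * v + (1.0 - beta) * f[t - 1]
        v_raw[t - 1] = v
        F[t - 1] = v / (1.0 - beta ** t)
        if mode == "literal":
            v = F[t - 1]
    return FHRSeries(f=f.copy(), F=F, beta=beta, v_raw=v_raw)


def rate_direct(peaks: PeakList) -> float:
    """Direct method: 60 over the plain mean of all intervals."""
    if len(peaks) < 2:
        raise InsufficientPeaksError("need >= 2 peaks for the direct method")
    return rate_from_interval(float(np.mean(np.diff(peaks.times))))


def rate_by_counting(peaks: PeakList, window_s: float) -> float:
    """Beat counting: peaks in the window scaled to a per-minute rate.

    Quantized at 60/window_s bpm per beat (15 bpm for 4 s windows)."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    return len(peaks) * 60.0 / window_s


def counting_resolution_bpm(window_s: float) -> float:
    """Smallest rate change the counting method can express: 60/window_s."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    return 60.0 / window_s


def influence_decay(beta: float) -> float:
    """Weight retained after 1/(1-beta) smoothing steps: beta**(1/(1-beta)).

    Approaches 1/e ~= 0.36 as beta -> 1; the smoothing memory is therefore
    about 1/(1-beta) windows.
    """
    if not 0 < beta < 1:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    return beta ** (1.0 / (1.0 - beta))


def extract_fhr(sig: AudioSegment, config: WindowConfig = WindowConfig(),
                beta: float = 0.9) -> FHRSeries:
    """Windowed fetal heart rate extraction over a whole recording.

    Decimates to the working rate, slides a [t, t+w) window by the hop,
    and per window runs peak detection, interval consensus, and rate
    conversion; the raw per-window rates are then smoothed by the
    bias-corrected EWMA.  Windows without a consensus (fewer than 3 peaks,
    or no two intervals within tolerance) reuse the neighbouring raw rate
    and are flagged.
    """
    if sig.duration < config.window_s:
        raise ValueError(
            f"signal of {sig.duration:.3f} s shorter than one "
            f"{config.window_s} s window"
        )
    work = sig
    if sig.sampling_rate != config.downsample_to:
        work = decimate(sig, config.downsample_to)
    fs = work.sampling_rate
    wn = int(round(config.window_s * fs))
    hn = int(round(config.hop_s * fs))
    starts = np.arange(0, len(work) - wn + 1, hn)

    f_raw = np.full(starts.size, np.nan)
    flagged = np.zeros(starts.size, dtype=bool)
    n_peaks = np.zeros(starts.size, dtype=int)
    consensus_size = np.zeros(starts.size, dtype=int)
    for k, s in enumerate(starts):
        window = AudioSegment(work.samples[s : s + wn], fs)
        peaks = detect_peaks(window, config)
        n_peaks[k] = len(peaks)
        try:
            cons = consensus_interval(peaks, config)
        except InsufficientPeaksError:
            flagged[k] = True
            logger.warning("window %d: %d peaks, consensus skipped", k, len(peaks))
            continue
        consensus_size[k] = cons.H.size
        if cons.H.size == 0 or not cons.A > 0:
            flagged[k] = True
            logger.warning("window %d: no intervals within tolerance", k)
            continue
        f_raw[k] = rate_from_interval(cons.A)

    if np.all(np.isnan(f_raw)):
        raise ValueError("no window produced an interval consensus")
    # carry the nearest successful raw rate into failed windows (forward
    # fill, with a backward fill for a failed run at the start)
    for k in range(1, f_raw.size):
        if np.isnan(f_raw[k]):
            f_raw[k] = f_raw[k - 1]
    for k in range(f_raw.size - 2, -1, -1):
        if np.isnan(f_raw[k]):
            f_raw[k] = f_raw[k + 1]

    series = ewma_bias_corrected(f_raw, beta)
    series.window_starts = starts / fs
    series.flagged = flagged
    series.n_peaks = n_peaks
    series.consensus_size = consensus_size
    return series
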