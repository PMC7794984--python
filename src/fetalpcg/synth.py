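"""Synthetic fetal phonocardiogram generator with known ground truth.

Fetal heart sounds occupy roughly the 10-400 Hz band and the normal fetal
heart rate is 120-160 bpm, i.e. about two cardiac cycles per second.  Each
cycle contributes two short sound bursts: S1 (louder, lower-pitched) and S2
(quieter, slightly higher-pitched), with S2 placed a systolic fraction of
the beat period after S1.  The generator models each burst as a
Hann-windowed sinusoid at known beat times, then contaminates the clean
signal with maternal heart sound (a slower, lower-frequency burst train),
broadband white noise, and powerline hum.  Because beat times and the clean
signal are returned as ground truth, every downstream stage (denoising SNR,
peak detection, rate extraction) can be scored exactly.

Also houses the instrumentation-amplifier gain formula of the acquisition
front end, G = 49.4 kOhm / R_G + 1, kept as a small utility.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Callable, Union

import numpy as np

from .audio import AudioSegment

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_pcg",
    "sensor_gain",
    "white_sigma_for_snr",
    "benchmark_config",
    "recovery_config",
    "write_ground_truth_csv",
    "DEFAULT_SEED",
]

#: seed of the packaged benchmark fixture
DEFAULT_SEED = 20210193

FhrTrajectory = Union[float, Callable[[float], float]]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic phonocardiogram generator.

    ``fhr_trajectory`` is either a constant rate in bpm or a callable
    mapping time in seconds to bpm; beat times are obtained by stepping
    60/fhr(t) from the first beat.  All amplitudes are pre-normalization
    units; the final mixture is rescaled by its max-abs to [-1, 1] and the
    clean signal is rescaled by the same factor, so noisy = clean + noise
    still holds after scaling.
    """

    sampling_rate: float = 8000.0
    duration: float = 8.0
    fhr_trajectory: FhrTrajectory = 140.0
    s1_center_freq: float = 35.0
    s2_center_freq: float = 60.0
    s1_amplitude: float = 1.0
    s2_amplitude: float = 0.5
    s1_duration: float = 0.06
    s2_duration: float = 0.04
    systolic_fraction: float = 0.35
    first_beat_s: float = 0.1
    noise_white_sigma: float = 0.0
    spike_rate: float = 0.0
    spike_amplitude: float = 1.0
    spike_duration: float = 0.002
    maternal_rate: float = 75.0
    maternal_amplitude: float = 0.0
    maternal_center_freq: float = 20.0
    maternal_burst_duration: float = 0.12
    powerline_freq: float = 50.0
    powerline_amplitude: float = 0.0
    seed: int = DEFAULT_SEED

    def fhr_at(self, t: float) -> float:
        if callable(self.fhr_trajectory):
            return float(self.fhr_trajectory(t))
        return float(self.fhr_trajectory)

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        for name in ("s1_amplitude", "s2_amplitude", "noise_white_sigma",
                     "maternal_amplitude", "powerline_amplitude",
                     "spike_rate", "spike_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        max_freq = max(self.s1_center_freq, self.s2_center_freq,
                       self.maternal_center_freq, self.powerline_freq)
        if self.sampling_rate <= 2 * max_freq:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} violates Nyquist for "
                f"component at {max_freq} Hz"
            )
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic_fraction must be in (0, 1)")
        # probe the trajectory at a few points
        for t in np.linspace(0.0, self.duration, 5):
            r = self.fhr_at(float(t))
            if not 0 < r < self.sampling_rate * 30:
                raise ValueError(f"fhr {r} bpm at t={t} outside (0, fs*30)")


@dataclass(frozen=True)
class GroundTruth:
    """Synthetic-only record of the clean signal and true beat times."""

    clean_signal: AudioSegment
    s1_times: np.ndarray = field(repr=False)
    s2_times: np.ndarray = field(repr=False)
    fhr_at: np.ndarray = field(repr=False)  # bpm aligned to s1_times

    def __post_init__(self) -> None:
        s1 = np.asarray(self.s1_times, dtype=np.float64)
        if s1.size > 1 and not np.all(np.diff(s1) > 0):
            raise ValueError("s1_times must be strictly increasing")


def _beat_times(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Beat (S1) times and the instantaneous rate at each beat."""
    times, rates = [], []
    t = config.first_beat_s
    while t < config.duration:
        r = config.fhr_at(t)
        times.append(t)
        rates.append(r)
        t += 60.0 / r
    return np.asarray(times), np.asarray(rates)


def _add_burst(out: np.ndarray, fs: float, center: float, freq: float,
               dur: float, amp: float) -> None:
    """Add a Hann-windowed sinusoid burst centered at `center` seconds."""
    n = out.size
    start = int(round((center - dur / 2) * fs))
    length = max(int(round(dur * fs)), 3)
    idx = np.arange(start, start + length)
    keep = (idx >= 0) & (idx < n)
    if not np.any(keep):
        return
    local = np.arange(length)[keep]
    env = np.hanning(length)[keep]
    tt = local / fs  # time within the burst
    out[idx[keep]] += amp * env * np.sin(2 * np.pi * freq * tt)


def _render_clean(config: SynthConfig) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray, np.ndarray]:
    """Pre-normalization clean burst train and its beat times."""
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    s1_times, fhr_at_beats = _beat_times(config)
    periods = 60.0 / fhr_at_beats
    s2_times = s1_times + config.systolic_fraction * periods
    s2_times = s2_times[s2_times < config.duration]
    clean = np.zeros(n)
    for tc in s1_times:
        _add_burst(clean, fs, tc, config.s1_center_freq,
                   config.s1_duration, config.s1_amplitude)
    for tc in s2_times:
        _add_burst(clean, fs, tc, config.s2_center_freq,
                   config.s2_duration, config.s2_amplitude)
    return clean, s1_times, s2_times, fhr_at_beats


def generate_pcg(config: SynthConfig) -> tuple[AudioSegment, GroundTruth]:
    """Generate a noisy fetal PCG and its ground truth.

    Returns
    -------
    noisy : AudioSegment
        clean + maternal + white noise + hum, max-abs normalized to [-1, 1].
    truth : GroundTruth
        Clean signal (same scaling as `noisy`), S1/S2 beat times, and the
        true rate at each beat.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    clean, s1_times, s2_times, fhr_at_beats = _render_clean(config)

    noise = np.zeros(n)
    if config.maternal_amplitude > 0:
        m_period = 60.0 / config.maternal_rate
        tm = rng.uniform(0, m_period)
        while tm < config.duration:
            _add_burst(noise, fs, tm, config.maternal_center_freq,
                       config.maternal_burst_duration,
                       config.maternal_amplitude)
            tm += m_period
    if config.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        noise += config.powerline_amplitude * np.sin(
            2 * np.pi * config.powerline_freq * t + phase)
    if config.spike_rate > 0:
        # impulsive "burr" artifacts (motion/friction clicks): a Poisson
        # train of short broadband clicks with random amplitude and sign
        n_spikes = rng.poisson(config.spike_rate * config.duration)
        for tc in np.sort(rng.uniform(0, config.duration, n_spikes)):
            amp = config.spike_amplitude * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
            width = max(int(round(config.spike_duration * fs)), 1)
            start = int(round(tc * fs))
            idx = np.arange(start, min(start + width, n))
            if idx.size:
                noise[idx] += amp * np.hanning(max(width, 2))[: idx.size]
    if config.noise_white_sigma > 0:
        noise += rng.normal(0.0, config.noise_white_sigma, n)

    noisy = clean + noise
    scale = np.max(np.abs(noisy))
    if scale > 0:
        noisy = noisy / scale
        clean = clean / scale

    truth = GroundTruth(
        clean_signal=AudioSegment(clean, fs),
        s1_times=s1_times,
        s2_times=s2_times,
        fhr_at=fhr_at_beats,
    )
    return AudioSegment(noisy, fs), truth


def sensor_gain(feedback_resistance_kohm: float) -> float:
    """Gain of the acquisition instrumentation amplifier.

    G = 49.4 kOhm / R_G + 1 with R_G in kOhm; e.g. R_G = 4.7 kOhm gives
    G = 11.51, the hardware's nominal x12 stage.
    """
    if not feedback_resistance_kohm > 0:
        raise ValueError(
            f"feedback resistance must be > 0 kOhm, got {feedback_resistance_kohm}"
        )
    return 49.4 / feedback_resistance_kohm + 1.0


def _decimation_noise_power_fraction(factor: int) -> float:
    """Fraction of white-noise power surviving zero-phase decimation.

    The anti-alias stage is an 8th-order Butterworth at 0.8x the target
    Nyquist applied forward-backward, so white noise is attenuated by
    |H(w)|^4; integer subsampling leaves the power unchanged.  Evaluated
    numerically from the filter's frequency response.
    """
    from scipy.signal import butter, freqz

    if factor == 1:
        return 1.0
    b, a = butter(8, 0.8 / factor)
    _, h = freqz(b, a, worN=8192)
    return float(np.mean(np.abs(h) ** 4))


def white_sigma_for_snr(config: SynthConfig, snr_db: float,
                        at_rate: float | None = None) -> float:
    """White-noise sigma giving the requested clean-vs-white-noise SNR.

    Renders the clean burst train of `config` (all noise off) at its
    pre-normalization scale and solves 10*log10(P_clean / P_white) = snr_db.
    With `at_rate`, the ratio is targeted after decimation to that working
    rate: the clean band (10-400 Hz) passes the anti-alias filter intact
    while broadband noise power is cut by the filter's noise bandwidth, so
    the in-band noise level — the one the denoisers actually face — is the
    controlled quantity.
    """
    config.validate()
    clean, _, _, _ = _render_clean(config)
    p_clean = float(np.mean(clean ** 2))
    if p_clean <= 0:
        raise ValueError("clean signal has zero power; cannot set SNR")
    keep = 1.0
    if at_rate is not None:
        factor = config.sampling_rate / at_rate
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("at_rate must divide the sampling rate")
        keep = _decimation_noise_power_fraction(int(round(factor)))
    return float(np.sqrt(p_clean / (keep * 10 ** (snr_db / 10))))


def benchmark_config(seed: int = DEFAULT_SEED, duration: float = 8.0,
                     fhr_bpm: float = 140.0,
                     input_snr_db: float = 5.0) -> SynthConfig:
    """The packaged denoising benchmark conditions.

    A constant-rate fetal PCG at the 8 kHz acquisition rate contaminated
    by every noise term of the model: white noise at a 5 dB
    clean-to-white ratio, impulsive "burr" clicks, maternal heart sound
    (kept modest, 0.1 — a smooth in-band interferent is irreducible for
    every denoiser alike, so it is a realism term rather than the
    dominant error source), and powerline hum.
    """
    base = SynthConfig(duration=duration, fhr_trajectory=fhr_bpm,
                       maternal_amplitude=0.1, powerline_amplitude=0.02,
                       spike_rate=4.0, seed=seed)
    sigma = white_sigma_for_snr(base, input_snr_db)
    return replace(base, noise_white_sigma=sigma)


def recovery_config(seed: int = DEFAULT_SEED, duration: float = 24.0,
                    fhr_bpm: float = 140.0,
                    input_snr_db: float = 5.0) -> SynthConfig:
    """Rate-recovery conditions: a constant-rate recording contaminated by
    white noise alone at a ~5 dB clean-to-noise ratio."""
    base = SynthConfig(duration=duration, fhr_trajectory=fhr_bpm, seed=seed)
    sigma = white_sigma_for_snr(base, input_snr_db)
    return replace(base, noise_white_sigma=sigma)


def write_ground_truth_csv(truth: GroundTruth, path) -> None:
    """Write beat events as CSV: time_s, event in {S1, S2}, fhr_bpm."""
    rows = [(t, "S1", r) for t, r in zip(truth.s1_times, truth.fhr_at)]
    rows += [(t, "S2", "") for t in truth.s2_times]
    rows.sort(key=lambda r: r[0])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "event", "fhr_bpm"])
        for t, ev, r in rows:
            w.writerow([f"{t:.6f}", ev, f"{r:.3f}" if r != "" else ""])
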