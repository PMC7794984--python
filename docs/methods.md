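# Methods

## Signal model and pretreatment

All processing operates on mono, double-precision samples. Pretreatment
removes the mean and rescales by the maximum absolute value to [−1, 1];
the SVR tube half-width ε and retrain threshold θ (both 0.1 by default)
are only meaningful on such a bounded scale, which is why normalization
is global per recording rather than per window. A constant input maps to
all-zeros (documented behaviour, not an error).

Decimation to the 1 kHz working rate used by rate extraction applies an
8th-order Butterworth low-pass at 0.8× the target Nyquist, forward and
backward (zero phase, so peak times are not shifted), then keeps every
k-th sample. Only integer factors are supported; 8 kHz → 1 kHz is the
intended path. Windowing uses half-open intervals [t, t+w) advanced by
the hop; a trailing partial window is discarded, so a T-second recording
yields ⌊(T−w)/hop⌋ + 1 windows.

## Adaptive ε-SVR denoising

Within each segment (default 0.5 s; 1.0 s selectable) the amplitude is
regressed on the time index scaled to [0, 1], with the Gaussian kernel
k(x, x′) = exp(−γ‖x−x′‖²). The standard ε-insensitive dual is solved
(the inner solver is scikit-learn's SVR; the test suite independently
verifies the solution against a generic convex-QP solve of the same dual
to 1e−4 on small instances). The regression curve is the denoised
segment; segments are concatenated and the result clipped to [−1, 1].

Hyperparameters are never set by hand. On the first segment (or when no
starting parameters are supplied) a grid search over
C ∈ {0.1, 1, 10, 100} × γ ∈ {10, 100, 1000, 3000, 10⁴} picks the pair
minimizing 5-fold cross-validated squared error, with a seeded shuffle
for fold assignment so the selection is reproducible. The γ range is set
by physics: the RBF length scale 1/√γ (in units of the 0.5 s segment)
must resolve the 35–60 Hz burst structure (17–29 ms period), while
length scales below ~3 ms would model sub-burst detail that is noise in
the 10–400 Hz heart-sound band — allowing larger γ lets the fit chase
impulsive artifacts and measurably degrades the recovered signal.

Each subsequent segment is first fitted with the current (C, γ); the
mean squared residual of that fit is the adaptation statistic. If it
exceeds θ the hyperparameters are re-learned on that segment and the
fit repeated; the per-segment MSE trace and retrain indices are
returned. The fit-MSE (rather than a held-out prediction error) is used
as the trigger because it is cheap, well-defined for every segment, and
directly measures whether the current smoothness assumptions still
describe the data. With θ = 0.1 retraining fires on regime changes
(e.g. a sudden amplitude/bandwidth change), not on ordinary noise.

The ε-insensitive loss is the reason this denoiser outperforms wavelet
thresholding in the presence of impulsive "burr" artifacts: samples
outside the tube contribute linearly (bounded influence, median-like
robustness), so a short click barely deflects the regression curve,
whereas a click's wavelet coefficients exceed any reasonable threshold
and pass into the wavelet reconstruction.

## Comparator denoisers

- **EMD.** In-package sifting with cubic-spline envelopes through local
  extrema, mirror-extended at the boundaries (two reflected extrema per
  end) to suppress spline end swings; a mode is accepted when the
  normalized squared change between sifting iterations falls below 0.2
  (Huang's SD criterion), and decomposition stops when the residue runs
  out of extrema or 10 modes are reached. Reconstruction keeps the
  ⌈K/2⌉ modes with the largest |correlation| against the *input* (ties
  prefer the lower-index, higher-frequency mode). Note a structural
  property: because the first modes carry most of any broadband noise,
  and that noise is part of the input the correlation is computed
  against, the kept half necessarily includes them — the scheme removes
  only low-correlation modes and is the weakest of the four denoisers,
  consistent with its placement in the comparison.
- **Adaptive LMS line enhancer.** 51 taps, step μ = 0.0014, reference =
  input delayed by 8 samples; taps update as w ← w + μ·e·u and the
  filter prediction is the output. Periodic content stays predictable
  across the delay; broadband noise decorrelates and is rejected.
- **Wavelet.** 6-level sym5 decomposition; noise scale estimated as
  MAD(finest detail)/0.6745; minimax threshold multiplier
  0.3936 + 0.1829·log₂(n) (0 for n ≤ 32); hard thresholding of detail
  coefficients only.

SNR is defined as 10·log₁₀(Σ clean² / Σ (estimate − clean)²) and is only
computable on synthetic data, where the generator provides the clean
reference on the same scale as the noisy mixture.

## Rate extraction

Peak detection (unspecified in the source method, chosen here): the
squared signal smoothed by a 20 ms moving average forms an energy
envelope; local maxima above 0.3× the window's envelope maximum,
separated by at least a 0.25 s refractory period, are taken as S1
events. The threshold rejects the quieter S2 (envelope ratio ≈ the
squared amplitude ratio, 0.25 for the default 2:1 S1:S2 amplitudes) and
the refractory period both caps the detectable rate at 240 bpm and
suppresses S2 events inside the systolic interval.

Interval consensus: the m−1 intervals are sorted descending into P; E
holds the m−2 adjacent differences; repeatedly the smallest remaining
E(i) is retired and P(i), P(i+1) join H (each position once). Two
stopping rules are provided. The *literal* transcription runs until
every difference is retired, which admits every interval and therefore
cannot reject outliers; the default *tolerance* mode stops once the
smallest remaining difference exceeds 0.05 s, so intervals produced by a
missed beat (≈ doubled) or a spurious detection never join H. H may
then be empty (no two intervals agree); such windows, and windows with
fewer than 3 peaks, are flagged and reuse the nearest successful raw
rate, since the smoother needs an input every step.

Smoothing: vₜ = β·vₜ₋₁ + (1−β)·fₜ from v₀ = 0 with the output
Fₜ = vₜ/(1−βᵗ). The division is applied at output time on an
uncorrected accumulator — equivalent to normalizing the geometric weight
sum — rather than feeding the corrected value back into the recursion; a
literal-feedback mode is kept behind a flag for comparison. The
correction makes constant inputs exact from the first window and decays
as βᵗ; after the memory length 1/(1−β) windows the retained weight is
β^(1/(1−β)) → 1/e ≈ 0.36 as β → 1 (0.349 at the default β = 0.9).

Baselines for comparison (`bench` subcommand): the direct method
(60 / plain mean of all intervals) and beat counting, whose output is
quantized at 60/w bpm — 15 bpm for 4 s windows.

## Synthetic data generator

Each cardiac cycle contributes an S1 burst (35 Hz, 60 ms, amplitude 1)
and an S2 burst (60 Hz, 40 ms, amplitude 0.5) placed a systolic fraction
(0.35) of the beat period after S1; bursts are Hann-windowed sinusoids,
so the envelope peak coincides with the (known) beat time. Beat times
step 60/fhr(t) from 0.1 s; the rate trajectory is a constant or a
callable, constrained to the physiologic 120–160 bpm in the packaged
conditions. Noise terms: maternal heart sound (20 Hz bursts, 120 ms, 75
bpm, random phase), white noise, powerline hum (50 Hz), and impulsive
"burr" clicks (a Poisson train, default 4/s in the benchmark, of 2 ms
Hann-windowed clicks with random sign and amplitude). The mixture is
rescaled by max-abs to [−1, 1] with the clean signal scaled identically,
so noisy = clean + noise survives normalization and SNR is well defined.
Identical config and seed give bit-identical output.

The packaged **benchmark** (8 s, 140 bpm, seed 20210193) sets the white
noise σ so that the clean-to-white ratio is 5 dB, includes burrs at 4/s,
maternal amplitude 0.1 and hum 0.02, and is denoised at the 8 kHz
acquisition rate (decimation belongs to rate extraction, not to the
denoising experiment). Maternal amplitude is deliberately modest: a
smooth in-band interferent is irreducible for every denoiser alike, so
at higher amplitude it becomes a common error floor that hides the
differences the comparison is meant to expose. The **recovery**
conditions (24 s, 140 bpm, white noise only at 5 dB) probe rate
extraction directly on the noisy signal.

What the synthetic experiments do and do not show: they verify the
algorithmic contracts exactly (beat times, clean references and rates
are known), but the burst model is stationary and stylized — real fetal
recordings have variable burst morphology, fetal movement, breathing
modulation, and maternal sounds that overlap the fetal band more
aggressively. Absolute SNR values on synthetic data therefore do not
transfer to clinical recordings; the *ordering* of methods and the
robustness mechanisms (tube loss vs thresholding, interval consensus vs
plain mean) are the transferable content.

## Numerical choices and degenerate inputs

- SVR solver tolerance 1e−6; predictions from the dual expansion are
  clipped to [−1, 1] at the denoiser boundary only.
- Cross-validation ties break toward the earlier grid entry;
  (C, γ) grids are ordered smooth-to-wiggly.
- A trailing denoising segment shorter than 2 samples merges into its
  predecessor.
- Consensus with equal minimal differences retires the lowest index
  first (matching the naive transcription used as the test oracle).
- Empty peak lists are valid detector output; consensus requires ≥ 3
  peaks and raises otherwise.
- WAV I/O is PCM16 mono with symmetric ±32767 scaling, so a write/read
  round trip is exact to half an LSB; out-of-range samples are clipped
  with a warning on write.
- 1/(1−β) sets the smoother's memory; β is validated to (0, 1)
  exclusive, and β → 0 degenerates to no smoothing.

## Known limitations

- EMD is a plain sifting implementation (no ensemble variant); mode
  mixing on strongly intermittent signals is expected.
- The LMS enhancer needs several seconds to converge at μ = 0.0014, so
  its measured SNR on short recordings includes the convergence
  transient.
- S1/S2 are not classified; the detector suppresses S2 by amplitude and
  refractory period, which fails if S2 ≈ S1 in amplitude.
- Only integer decimation factors are supported.
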