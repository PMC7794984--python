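# fetalpcg

Fetal phonocardiogram (PCG) processing: denoising of fetal heart sound
recordings and extraction of the fetal heart rate (FHR), for researchers
and engineers working on passive acoustic fetal monitoring.

Fetal heart sounds occupy roughly 10–400 Hz and the normal fetal heart
rate lies between 120 and 160 bpm, i.e. about two cardiac cycles per
second. A recording captured on the maternal abdomen is contaminated by
maternal heart sound, broadband sensor noise, impulsive motion artifacts
("burrs"), and powerline hum. This package implements:

- **Adaptive ε-SVR denoising.** Each 0.5 s segment is denoised by
  regressing amplitude on time with a Gaussian-kernel support vector
  regression; the regression curve f(t) = Σᵢ aᵢ k(tᵢ, t) + b is the
  "center line" through the noise band. The hyperparameters (C, γ) are
  self-learned by k-fold cross-validated grid search, and whenever the
  mean squared fit residual of a new segment exceeds a threshold θ
  (default 0.1 on the normalized amplitude scale, like the tube width
  ε = 0.1) they are re-learned on that segment.
- **Comparator denoisers** with their literature-standard settings: EMD
  (10 modes, reconstruction from the half most correlated with the
  input), an adaptive LMS line enhancer (51 taps, step 0.0014), and sym5
  wavelet thresholding (6 levels, minimax threshold, hard shrinkage).
- **FHR extraction.** At a 1 kHz working rate, a 4 s window sliding by
  1 s detects S1 peaks on a smoothed energy envelope; the peak intervals
  are sorted descending into P, adjacent differences form E, and mutually
  similar intervals are greedily collected into H (an interval distorted
  by a missed or spurious beat never joins), giving a robust mean
  interval A and window rate fₜ = 60/A. Between windows the rates are
  smoothed by a bias-corrected exponentially weighted moving average
  vₜ = β·vₜ₋₁ + (1−β)·fₜ, Fₜ = vₜ/(1−βᵗ) with β = 0.9.
- **A synthetic PCG generator** producing recordings with exact ground
  truth (clean signal, beat times, true rate trajectory), so every stage
  is scored without clinical data.

## Worked example

```python
import fetalpcg as fp

cfg = fp.benchmark_config(seed=fp.DEFAULT_SEED)   # 8 s at 140 bpm, 8 kHz
noisy, truth = fp.generate_pcg(cfg)
print(f"input SNR: {fp.snr_db(truth.clean_signal, noisy):.2f} dB")

report = fp.adaptive_svr_denoise(noisy, seed=1)
print(f"adaptive SVR SNR: {fp.snr_db(truth.clean_signal, report.output):.2f} dB")
print(f"selected C={report.state.current_params.C}, "
      f"gamma={report.state.current_params.gamma}")

series = fp.extract_fhr(fp.generate_pcg(fp.recovery_config(seed=1))[0],
                        fp.WindowConfig(), beta=0.9)
print(f"{series.f.size} windows, smoothed rate "
      f"{series.F[-1]:.2f} bpm (true 140)")
```

prints

```
input SNR: 3.67 dB
adaptive SVR SNR: 10.28 dB
selected C=1.0, gamma=10000.0
21 windows, smoothed rate 139.99 bpm (true 140)
```

The denoiser raised the SNR against the known clean signal by ~7 dB, the
cross-validation selected a kernel bandwidth able to track the 35–60 Hz
heart-sound bursts, and the windowed consensus + smoothing recovered the
true rate to well within a beat per minute despite the ≈5 dB input noise.

The same pipeline is available from the shell:

```bash
fetalpcg synth --duration 8 --fhr 140 --noise-sigma 0.2 --seed 1 --out rec.wav
fetalpcg denoise --method svr --in rec.wav --out den.wav
fetalpcg fhr --in den.wav --window 4 --hop 1 --beta 0.9 --out rates.csv
fetalpcg pipeline examples/pipeline.yaml
```

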