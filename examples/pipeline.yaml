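# End-to-end example: synthesize a noisy recording, denoise it with the
# adaptive SVR, and extract the smoothed fetal heart rate.
seed: 1
synth:
  duration: 8.0
  fhr_trajectory: 140.0
  noise_white_sigma: 0.2
  maternal_amplitude: 0.1
  powerline_amplitude: 0.02
  seed: 1
denoise:
  method: adaptive_svr
  segment_s: 0.5
fhr:
  window_s: 4.0
  hop_s: 1.0
  beta: 0.9
output:
  dir: pipeline_out
  prefix: example
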