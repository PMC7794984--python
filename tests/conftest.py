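import numpy as np
import pytest

import fetalpcg as fp


@pytest.fixture(scope="session")
def benchmark_recording():
    """The packaged fixed-seed denoising benchmark: noisy 8 kHz recording
    plus ground truth."""
    cfg = fp.benchmark_config(seed=fp.DEFAULT_SEED)
    sig, truth = fp.generate_pcg(cfg)
    return sig, truth


@pytest.fixture(scope="session")
def benchmark_reports(benchmark_recording):
    """All four denoisers run once on the benchmark, with SNRs filled in."""
    sig, truth = benchmark_recording
    clean = truth.clean_signal
    reports = {
        "adaptive_svr": fp.adaptive_svr_denoise(sig, seed=1),
        "emd": fp.emd_denoise(sig),
        "lms": fp.lms_denoise(sig),
        "wavelet": fp.wavelet_denoise(sig),
    }
    for rep in reports.values():
        rep.snr_db = fp.snr_db(clean, rep.output)
    return reports


@pytest.fixture(scope="session")
def quiet_recording():
    """Zero-noise 24 s recording at a constant 140 bpm."""
    cfg = fp.SynthConfig(duration=24.0, fhr_trajectory=140.0, seed=3)
    return fp.generate_pcg(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
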