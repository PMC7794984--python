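import numpy as np
import pytest

import fetalpcg as fp
from fetalpcg.audio import AudioSegment
from fetalpcg.denoise import SVRParams, fit_svr, tune_svr
from helpers import qp_svr_predict


def _noisy_instance(seed, n):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, n))
    y = 0.8 * t - 0.3 + 0.15 * np.sin(6 * t) + rng.normal(0, 0.08, n)
    return t, y


class TestFitSvr:
    @pytest.mark.parametrize("seed,n,C,gamma", [
        (0, 10, 1.0, 1.0),
        (1, 12, 1.0, 5.0),
        (2, 15, 10.0, 1.0),
        (3, 8, 0.5, 20.0),
        (4, 15, 100.0, 10.0),
    ])
    def test_matches_generic_qp_dual_solution(self, seed, n, C, gamma):
        """Predictions agree with an independent convex-QP solve of the
        same epsilon-insensitive dual to 1e-4."""
        t, y = _noisy_instance(seed, n)
        eps = 0.1
        model = fit_svr(t, y, SVRParams(C=C, gamma=gamma, epsilon=eps))
        grid = np.linspace(0, 1, 31)
        oracle_pred, _, _ = qp_svr_predict(t, y, C, gamma, eps, grid)
        np.testing.assert_allclose(model.predict(grid), oracle_pred, atol=1e-4)

    @pytest.mark.parametrize("seed", range(6))
    def test_dual_feasibility_and_kkt(self, seed):
        t, y = _noisy_instance(seed, 40)
        params = SVRParams(C=2.0, gamma=10.0, epsilon=0.1)
        model = fit_svr(t, y, params)
        assert np.all(np.abs(model.dual_coefficients) <= params.C + 1e-8)
        # points strictly inside the tube carry no dual weight: every
        # support vector must sit on or outside the tube
        resid = np.abs(model.predict(model.support_inputs)
                       - y[np.searchsorted(t, model.support_inputs)])
        assert np.all(resid >= params.epsilon - 1e-3)

    def test_constant_target_predicted_within_epsilon(self):
        t = np.linspace(0, 1, 20)
        y = np.full(20, 0.4)
        model = fit_svr(t, y, SVRParams(C=1.0, gamma=10.0, epsilon=0.1))
        assert np.all(np.abs(model.predict(t) - 0.4) <= 0.1 + 1e-8)

    def test_targets_inside_tube_leave_no_support_vectors(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 30)
        y = 0.2 + rng.uniform(-0.04, 0.04, 30)  # spread < epsilon
        model = fit_svr(t, y, SVRParams(C=1.0, gamma=10.0, epsilon=0.1))
        assert model.dual_coefficients.size == 0
        np.testing.assert_allclose(model.predict(t), model.bias)
        assert abs(model.bias - 0.2) <= 0.1

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_svr([0.5], [1.0], SVRParams())


class TestTuneSvr:
    def _segment(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / (n - 1)
        y = 0.7 * np.sin(2 * np.pi * 3 * t) + rng.normal(0, 0.1, n)
        return AudioSegment(np.clip(y, -1, 1), float(n))

    def test_singleton_grid_returned(self):
        seg = self._segment()
        params = tune_svr(seg, grid=[(3.0, 7.0)], folds=3, seed=0)
        assert (params.C, params.gamma) == (3.0, 7.0)

    def test_deterministic_given_seed(self):
        seg = self._segment()
        a = tune_svr(seg, folds=5, seed=42)
        b = tune_svr(seg, folds=5, seed=42)
        assert (a.C, a.gamma) == (b.C, b.gamma)

    def test_selection_minimizes_cv_mse_over_grid(self):
        """Exhaustive re-evaluation of the grid is the oracle: no grid
        point may beat the selected one."""
        from sklearn.model_selection import KFold

        seg = self._segment(seed=5)
        grid = [(0.1, 10.0), (1.0, 10.0), (1.0, 100.0), (10.0, 1000.0)]
        chosen = tune_svr(seg, grid=grid, folds=4, seed=7)
        y = seg.samples
        t = np.arange(y.size) / (y.size - 1)
        splits = list(KFold(4, shuffle=True, random_state=7).split(t))

        def cv_mse(C, gamma):
            total = 0.0
            for tr, te in splits:
                m = fit_svr(t[tr], y[tr], SVRParams(C, gamma, 0.1, 0.1))
                total += float(np.mean((m.predict(t[te]) - y[te]) ** 2))
            return total / len(splits)

        chosen_mse = cv_mse(chosen.C, chosen.gamma)
        for C, gamma in grid:
            assert chosen_mse <= cv_mse(C, gamma) + 1e-12

    def test_fewer_samples_than_folds_rejected(self):
        seg = AudioSegment(np.zeros(3), 1000.0)
        with pytest.raises(ValueError):
            tune_svr(seg, folds=5, seed=0)


class TestAdaptiveSvr:
    def test_zero_signal_maps_to_zero_without_retraining(self):
        seg = AudioSegment(np.zeros(2000), 1000.0)
        rep = fp.adaptive_svr_denoise(seg, seed=0)
        np.testing.assert_allclose(rep.output.samples, 0.0, atol=1e-6)
        assert rep.state.retrain_events == []

    def test_benchmark_snr_improves_by_6db(self, benchmark_recording,
                                           benchmark_reports):
        sig, truth = benchmark_recording
        input_snr = fp.snr_db(truth.clean_signal, sig)
        out_snr = benchmark_reports["adaptive_svr"].snr_db
        assert out_snr >= input_snr + 6.0

    def test_regime_change_triggers_retraining(self):
        """A quiet first half followed by loud broadband activity must push
        the fit MSE over theta and retune at least once in the second half."""
        rng = np.random.default_rng(0)
        n = 4000
        first = 0.05 * np.sin(2 * np.pi * 2 * np.arange(n // 2) / 1000.0)
        second = np.clip(rng.normal(0, 0.6, n // 2), -1, 1)
        seg = AudioSegment(np.concatenate([first, second]), 1000.0)
        rep = fp.adaptive_svr_denoise(seg, seed=0)
        n_segments = rep.info["n_segments"]
        assert any(k >= n_segments // 2 for k in rep.state.retrain_events)
        theta = rep.state.current_params.theta
        assert any(m > theta for m in rep.state.mse_trace)

    def test_mse_trace_and_events_consistent(self, benchmark_reports):
        state = benchmark_reports["adaptive_svr"].state
        assert all(m >= 0 for m in state.mse_trace)
        theta = state.current_params.theta
        for k in state.retrain_events:
            assert state.mse_trace[k] > theta

    def test_constant_signal_stays_constant_within_epsilon(self):
        seg = AudioSegment(np.full(2000, 0.4), 1000.0)
        rep = fp.adaptive_svr_denoise(seg, seed=0)
        eps = rep.state.current_params.epsilon
        assert np.all(np.abs(rep.output.samples - 0.4) <= eps + 1e-8)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            fp.adaptive_svr_denoise(AudioSegment(np.empty(0), 1000.0))


class TestEmd:
    def test_decomposition_is_complete(self, rng):
        x = np.cumsum(rng.normal(size=1500)) / 30.0
        imfs, residue = fp.emd(x, max_imfs=10)
        np.testing.assert_allclose(np.sum(imfs, axis=0) + residue, x,
                                   atol=1e-9)
        assert 1 <= len(imfs) <= 10

    def test_output_length_preserved(self, rng):
        seg = AudioSegment(np.clip(rng.normal(0, 0.2, 3000), -1, 1), 1000.0)
        rep = fp.emd_denoise(seg)
        assert len(rep.output) == len(seg)
        assert rep.output.sampling_rate == seg.sampling_rate

    def test_sine_in_noise_selection_contract(self, rng):
        """Top-half-by-correlation selection keeps the mode carrying the
        sine (and, with it, the dominant share of signal correlation);
        the discarded modes are the low-correlation ones."""
        t = np.arange(4000) / 1000.0
        clean = 0.6 * np.sin(2 * np.pi * 30 * t)
        noisy = np.clip(clean + rng.normal(0, 0.3, t.size), -1, 1)
        rep = fp.emd_denoise(AudioSegment(noisy, 1000.0))
        corrs = np.abs(rep.info["correlations"])
        kept = rep.info["kept"]
        discarded = [i for i in range(rep.info["n_imfs"]) if i not in kept]
        assert int(np.argmax(corrs)) in kept
        if discarded:
            assert max(corrs[i] for i in discarded) <= min(
                corrs[i] for i in kept) + 1e-12
        c_before = np.corrcoef(clean, noisy)[0, 1]
        c_after = np.corrcoef(clean, rep.output.samples)[0, 1]
        assert c_after > 0.95 * c_before

    def test_keeps_half_the_imfs(self, rng):
        seg = AudioSegment(np.clip(rng.normal(0, 0.2, 3000), -1, 1), 1000.0)
        rep = fp.emd_denoise(seg, layers=10)
        k = rep.info["n_imfs"]
        assert len(rep.info["kept"]) == -(-k // 2)  # ceil(k/2)


class TestLms:
    def test_zero_input_zero_output(self):
        seg = AudioSegment(np.zeros(1000), 1000.0)
        rep = fp.lms_denoise(seg)
        np.testing.assert_array_equal(rep.output.samples, 0.0)

    def test_converges_on_stationary_sinusoid(self):
        t = np.arange(8000) / 1000.0
        seg = AudioSegment(0.8 * np.sin(2 * np.pi * 40 * t), 1000.0)
        rep = fp.lms_denoise(seg)
        err = seg.samples - rep.output.samples
        n = err.size
        assert np.mean(err[-n // 10:] ** 2) < np.mean(err[: n // 10] ** 2)

    def test_output_length_preserved(self, rng):
        seg = AudioSegment(np.clip(rng.normal(0, 0.3, 2500), -1, 1), 1000.0)
        rep = fp.lms_denoise(seg)
        assert len(rep.output) == 2500

    def test_non_positive_learning_rate_rejected(self):
        seg = AudioSegment(np.zeros(100), 1000.0)
        with pytest.raises(ValueError):
            fp.lms_denoise(seg, mu=0.0)


class TestWavelet:
    def test_zero_input_zero_output(self):
        seg = AudioSegment(np.zeros(2000), 1000.0)
        rep = fp.wavelet_denoise(seg)
        np.testing.assert_allclose(rep.output.samples, 0.0, atol=1e-12)

    def test_zero_threshold_reconstructs_input(self, rng):
        seg = AudioSegment(np.clip(rng.normal(0, 0.3, 2048), -1, 1), 1000.0)
        rep = fp.wavelet_denoise(seg, threshold=0.0)
        np.testing.assert_allclose(rep.output.samples, seg.samples, atol=1e-10)

    def test_benchmark_snr_improves(self, benchmark_recording, benchmark_reports):
        sig, truth = benchmark_recording
        assert benchmark_reports["wavelet"].snr_db > fp.snr_db(truth.clean_signal, sig)

    def test_too_short_signal_rejected(self):
        seg = AudioSegment(np.zeros(40), 1000.0)
        with pytest.raises(ValueError):
            fp.wavelet_denoise(seg)


class TestSnr:
    def _clean(self):
        t = np.arange(1000) / 1000.0
        return AudioSegment(0.5 * np.sin(2 * np.pi * 10 * t), 1000.0)

    def test_zero_estimate_gives_zero_db(self):
        clean = self._clean()
        zeros = AudioSegment(np.zeros(len(clean)), 1000.0)
        assert fp.snr_db(clean, zeros) == pytest.approx(0.0, abs=1e-9)

    def test_ten_percent_scaling_error_gives_20db(self):
        clean = self._clean()
        est = AudioSegment(clean.samples * 1.1, 1000.0)
        assert fp.snr_db(clean, est) == pytest.approx(20.0, abs=1e-9)

    def test_perfect_estimate_gives_infinity(self):
        clean = self._clean()
        assert fp.snr_db(clean, clean) == np.inf

    def test_length_mismatch_rejected(self):
        clean = self._clean()
        short = AudioSegment(clean.samples[:-1], 1000.0)
        with pytest.raises(ValueError):
            fp.snr_db(clean, short)

    def test_zero_clean_energy_rejected(self):
        zeros = AudioSegment(np.zeros(100), 1000.0)
        with pytest.raises(ValueError):
            fp.snr_db(zeros, zeros)


class TestContracts:
    def test_all_denoisers_preserve_length_and_rate(self, benchmark_recording,
                                                    benchmark_reports):
        sig, _ = benchmark_recording
        for rep in benchmark_reports.values():
            assert len(rep.output) == len(sig)
            assert rep.output.sampling_rate == sig.sampling_rate

    def test_unknown_method_rejected_with_choices(self):
        seg = AudioSegment(np.zeros(100), 1000.0)
        with pytest.raises(ValueError, match="wavelet"):
            fp.denoise(seg, "fourier")
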