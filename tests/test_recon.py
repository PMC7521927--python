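import numpy as np
import pytest

import vestcode as vc
from vestcode.recon import ReconSettings
from vestcode.spikes import binarize

from conftest import least_squares_fir, least_squares_fir_pair

ORACLE_SETTINGS = ReconSettings(window_s=4.096, overlap=0.75, n_tapers=5,
                                max_freq=50.0, taper_frac=0.05,
                                kernel_halfwidth_s=0.2)


@pytest.fixture(scope="module")
def wiener_instance():
    """60 s regular high-sensitivity neuron pair for decoder checks."""
    stim = vc.generate_naturalistic_stimulus(
        vc.StimulusSpec(duration=60.0, seed=11))
    r1 = vc.generate_ln_response(
        stim, vc.NeuronSpec(base_rate=60.0, target_cv=0.1, sensitivity=0.5,
                            kernel_shape="identity", seed=12))
    r2 = vc.generate_ln_response(
        stim, vc.NeuronSpec(base_rate=55.0, target_cv=0.15, sensitivity=0.4,
                            kernel_shape="identity", seed=13))
    return stim, r1, r2


class TestSingleKernel:
    def test_self_reconstruction_of_a_trace(self, stimulus_120):
        res = vc.reconstruct_and_score(vc.Trace(stimulus_120.values.copy()),
                                       stimulus_120)
        assert res.cf > 0.98
        k = res.kernels[0]
        assert abs(k.lags[np.argmax(np.abs(k.values))]) < 0.002

    def test_scaled_input_halves_the_kernel(self, stimulus_120):
        k1 = vc.optimal_kernel_single(vc.Trace(stimulus_120.values.copy()),
                                      stimulus_120)
        k2 = vc.optimal_kernel_single(vc.Trace(2.0 * stimulus_120.values),
                                      stimulus_120)
        assert np.allclose(k2.values, k1.values / 2.0, atol=1e-6)

    def test_empty_spike_train_rejected(self, stimulus_120):
        silent = np.zeros(stimulus_120.n_samples)
        with pytest.raises(ValueError, match="empty"):
            vc.optimal_kernel_single(silent, stimulus_120)

    def test_matches_least_squares_fir_oracle(self, wiener_instance):
        stim, r1, _ = wiener_instance
        k = vc.optimal_kernel_single(r1, stim, settings=ORACLE_SETTINGS)
        n_lags = (k.values.size - 1) // 2
        h = least_squares_fir(binarize(r1), stim.values, n_lags)
        rel = np.sqrt(np.mean((k.values - h) ** 2)) / np.sqrt(np.mean(h**2))
        assert rel < 0.02


class TestPairKernel:
    def test_uninformative_partner_contributes_nothing(self, wiener_instance):
        stim, r1, _ = wiener_instance
        noise = vc.generate_renewal_spiketrain(50.0, 0.5, 60.0, seed=44)
        k1, k2, flags = vc.optimal_kernel_pair(r1, noise, stim,
                                               settings=ORACLE_SETTINGS)
        assert np.sqrt(np.mean(k2.values**2)) < \
            0.2 * np.sqrt(np.mean(k1.values**2))
        single = vc.reconstruct_and_score(r1, stim, settings=ORACLE_SETTINGS)
        pair = vc.reconstruct_and_score([r1, noise], stim,
                                        settings=ORACLE_SETTINGS)
        assert pair.cf == pytest.approx(single.cf, abs=0.02)

    def test_duplicated_neuron_falls_back_with_warning(self, wiener_instance):
        stim, r1, _ = wiener_instance
        with pytest.warns(UserWarning, match="singular"):
            k1, k2, flags = vc.optimal_kernel_pair(r1, r1, stim,
                                                   settings=ORACLE_SETTINGS)
        assert flags["singular_fallback"]
        assert not k2.values.any()

    def test_pair_cf_matches_least_squares_oracle(self, wiener_instance):
        from scipy.signal import fftconvolve
        stim, r1, r2 = wiener_instance
        res = vc.reconstruct_and_score([r1, r2], stim,
                                       settings=ORACLE_SETTINGS)
        n_lags = (res.kernels[0].values.size - 1) // 2
        b1, b2 = binarize(r1), binarize(r2)
        h1, h2 = least_squares_fir_pair(b1, b2, stim.values, n_lags)
        rec = fftconvolve(b1 - b1.mean(), h1, mode="same") + \
            fftconvolve(b2 - b2.mean(), h2, mode="same")
        cf_ls, _ = vc.coding_fraction(stim, vc.Trace(rec), res.valid)
        assert res.cf == pytest.approx(cf_ls, abs=0.02 * cf_ls)

    def test_pair_beats_or_matches_best_single(self, wiener_instance):
        stim, r1, r2 = wiener_instance
        cf1 = vc.reconstruct_and_score(r1, stim, settings=ORACLE_SETTINGS).cf
        cf2 = vc.reconstruct_and_score(r2, stim, settings=ORACLE_SETTINGS).cf
        cf_pair = vc.reconstruct_and_score([r1, r2], stim,
                                           settings=ORACLE_SETTINGS).cf
        assert cf_pair >= max(cf1, cf2) - 0.005

    def test_low_cv_pair_outperforms_mixed_pair(self, stimulus_120):
        # matched cohorts: pairing two regular neurons reconstructs better
        # than pairing a regular with an irregular one
        mk = lambda cv, seed: vc.generate_ln_response(
            stimulus_120, vc.NeuronSpec(base_rate=55.0, target_cv=cv,
                                        sensitivity=0.5,
                                        kernel_shape="identity", seed=seed))
        low1, low2, high = mk(0.1, 61), mk(0.12, 62), mk(0.7, 63)
        cf_low = vc.reconstruct_and_score([low1, low2], stimulus_120).cf
        cf_mixed = vc.reconstruct_and_score([low1, high], stimulus_120).cf
        assert cf_low >= cf_mixed


class TestReconstruct:
    def test_zero_kernel_reconstructs_nothing(self, wiener_instance):
        stim, r1, _ = wiener_instance
        k = vc.optimal_kernel_single(r1, stim, settings=ORACLE_SETTINGS)
        zero = vc.Kernel(k.lags, np.zeros_like(k.values))
        rec, valid = vc.reconstruct(r1, zero, n_samples=stim.n_samples)
        assert not rec.values.any()

    def test_impulse_kernel_on_identical_signal_is_identity(self):
        x = np.random.default_rng(9).standard_normal(30000)
        impulse = vc.Kernel(np.arange(-5, 6) / 1000.0,
                            np.eye(11)[5])
        rec, valid = vc.reconstruct(x, impulse, fs=1000.0)
        assert np.allclose(rec.values[valid], (x - x.mean())[valid])

    def test_time_shift_with_refit_leaves_cf_unchanged(self, wiener_instance):
        stim, r1, _ = wiener_instance
        base = vc.reconstruct_and_score(r1, stim, settings=ORACLE_SETTINGS)
        shifted = vc.SpikeTrain(
            (r1.times + 0.010)[r1.times + 0.010 < r1.duration],
            duration=r1.duration)
        refit = vc.reconstruct_and_score(shifted, stim,
                                         settings=ORACLE_SETTINGS)
        assert refit.cf == pytest.approx(base.cf, abs=0.01)

    def test_seam_samples_excluded_from_scoring(self, wiener_instance):
        stim, r1, _ = wiener_instance
        segments = [(0, 30000), (30000, 60000)]
        res = vc.reconstruct_and_score(r1, stim, segments=segments,
                                       settings=ORACLE_SETTINGS)
        half = (res.kernels[0].values.size - 1) // 2
        assert not res.valid[30000 - half:30000 + half].any()


class TestCodingFraction:
    def test_perfect_reconstruction_scores_one(self, stimulus_120):
        cf, _ = vc.coding_fraction(stimulus_120,
                                   vc.Trace(stimulus_120.values.copy()))
        assert cf == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self, stimulus_120):
        mean_trace = vc.Trace(np.full(stimulus_120.n_samples,
                                      stimulus_120.values.mean()))
        cf, _ = vc.coding_fraction(stimulus_120, mean_trace)
        assert cf == pytest.approx(0.0, abs=1e-9)

    def test_constant_stimulus_rejected(self):
        flat = vc.Trace(np.full(20000, 3.0))
        with pytest.raises(ValueError, match="variance"):
            vc.coding_fraction(flat, flat)

    def test_gaussian_channel_matches_wiener_mse_closed_form(self):
        # R = S + white noise; CF = 1 - sqrt(int Pss(1-C) / int Pss)
        rng = np.random.default_rng(42)
        stim = vc.generate_naturalistic_stimulus(
            vc.StimulusSpec(duration=120.0, seed=42))
        noise_sd = 20.0
        resp = vc.Trace(stim.values + noise_sd *
                        rng.standard_normal(stim.n_samples))
        res = vc.reconstruct_and_score(resp, stim, settings=ORACLE_SETTINGS)
        s_est = vc.power_spectrum(
            stim, settings=vc.SpectralSettings(window_s=4.096, overlap=0.75))
        p_nn = 2.0 * noise_sd**2 / 1000.0  # one-sided density of the noise
        c = s_est.power / (s_est.power + p_nn)
        cf_pred = 1.0 - np.sqrt(
            np.trapezoid(s_est.power * (1 - c), s_est.freqs) /
            np.trapezoid(s_est.power, s_est.freqs))
        assert res.cf == pytest.approx(cf_pred, abs=0.03 * cf_pred)

    def test_kernel_gain_perturbation_strictly_hurts(self, wiener_instance):
        stim, r1, _ = wiener_instance
        res = vc.reconstruct_and_score(r1, stim, settings=ORACLE_SETTINGS)
        k = res.kernels[0]
        for gain in (0.95, 1.05):
            scaled = vc.Kernel(k.lags, gain * k.values)
            rec, valid = vc.reconstruct(r1, scaled, n_samples=stim.n_samples)
            cf, _ = vc.coding_fraction(stim, rec, valid)
            assert cf < res.cf

    def test_cf_decreases_with_variability_across_cohort(self, cohort_run):
        from scipy.stats import spearmanr
        table, _ = cohort_run
        assert spearmanr(table["cv"], table["cf"]).statistic < -0.9
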