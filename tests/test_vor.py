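import numpy as np
import pytest

import vestcode as vc
from vestcode.vor import VORParams, ni_plant_response, stage_response

PROBE_FREQS = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0)


class TestStageResponses:
    def test_ni_plant_product_is_delayed_first_order_lowpass(self):
        p = VORParams()
        for f in PROBE_FREQS:
            product = stage_response(p, f, "ni") * stage_response(p, f, "plant")
            s = 2j * np.pi * f
            expected = np.exp(-s * p.tau) / (s * p.Te2 + 1)
            assert product == pytest.approx(expected, rel=1e-12)
        # closed-form magnitude at 1 Hz
        mag = abs(ni_plant_response(p, 1.0))
        assert mag == pytest.approx(1 / np.sqrt(1 + (2 * np.pi * 0.016) ** 2),
                                    rel=1e-12)

    def test_simplified_ni_plant_matches_stage_product(self):
        p = VORParams()
        f = np.array(PROBE_FREQS)
        prod = stage_response(p, f, "ni") * stage_response(p, f, "plant")
        assert np.allclose(ni_plant_response(p, f), prod, rtol=1e-12)

    def test_delay_contributes_exact_linear_phase(self):
        p = VORParams()
        for f in (1.0, 7.0, 19.0):
            no_delay = VORParams(tau=1e-12)
            ratio = stage_response(p, f, "plant") / \
                stage_response(no_delay, f, "plant")
            assert np.angle(ratio) == pytest.approx(-2 * np.pi * f * p.tau,
                                                    abs=1e-9)

    def test_sensory_cascade_has_unit_gain_at_one_hertz(self):
        p = VORParams(g_VOR=1.0)
        v = stage_response(p, 1.0, "afferents") * stage_response(p, 1.0, "vn")
        s = 2j * np.pi * 1.0
        expected = abs(s * p.T_VOR * (1 + s * p.T1) /
                       ((1 + s * p.T2) * (1 + s * p.T_VOR)))
        assert abs(v) == pytest.approx(expected, rel=1e-12)
        assert abs(v) == pytest.approx(1.0, abs=0.01)

    def test_canal_constant_cancels_in_sensory_cascade(self):
        # velocity storage replaces the canal constant: the composite gain
        # is insensitive to +/-10% changes in Tc at f >= 0.5 Hz
        f = np.array(PROBE_FREQS)
        base = VORParams()
        ref = stage_response(base, f, "afferents") * \
            stage_response(base, f, "vn")
        for scale in (0.9, 1.1):
            p = VORParams(Tc=5.7 * scale)
            v = stage_response(p, f, "afferents") * stage_response(p, f, "vn")
            assert np.all(np.abs(np.abs(v) / np.abs(ref) - 1.0) < 0.005)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_response(VORParams(), 1.0, "cortex")


class TestSimulateVor:
    def test_zero_head_gives_zero_eye(self):
        eye = vc.simulate_vor(vc.Trace(np.zeros(4000)))
        assert not eye.values.any()

    def test_sinusoidal_probes_match_closed_form(self):
        # FFT simulation vs analytic gain/phase at six probe frequencies
        p = VORParams()
        fs = 1000.0
        t = np.arange(0, 40.0, 1 / fs)
        for f in PROBE_FREQS:
            head = vc.Trace(30.0 * np.sin(2 * np.pi * f * t))
            eye = vc.simulate_vor(head, p)
            target = vc.total_response(p, f)
            m = slice(int(4 * fs), int(36 * fs))
            gain = np.std(eye.values[m]) / np.std(head.values[m])
            assert gain == pytest.approx(abs(target), rel=0.02)
            # phase from the cross-spectral angle at the probe frequency
            seg = np.conj(np.fft.rfft(head.values[m])) * \
                np.fft.rfft(eye.values[m])
            idx = np.argmax(np.abs(seg))
            phase = np.angle(seg[idx])
            err = np.angle(np.exp(1j * (phase - np.angle(target))))
            assert abs(np.degrees(err)) < 3.0

    def test_naturalistic_gain_near_unity(self, stimulus_120):
        eye = vc.simulate_vor(stimulus_120, VORParams(g_VOR=1.0))
        gain, diag = vc.vor_gain(stimulus_120, eye)
        assert 0.85 <= gain <= 1.05

    def test_reduced_reflex_gain_tracked_by_regression(self, stimulus_120):
        eye = vc.simulate_vor(stimulus_120, VORParams(g_VOR=0.9))
        gain, _ = vc.vor_gain(stimulus_120, eye)
        assert 0.85 <= gain <= 0.95


class TestPredictEyeFromSpikes:
    def test_model_consistent_drive_reproduces_simulation(self, stimulus_120):
        # noiseless binarized model drive through NI+plant matches the
        # head->eye simulation spectrum inside the estimator CI
        p = VORParams()
        spec = vc.NeuronSpec(base_rate=80.0, target_cv=0.05, sensitivity=1.0,
                             kernel_shape="vor", seed=5, vor_params=p)
        train = vc.generate_ln_response(stimulus_120, spec)
        _, pred = vc.predict_eye_from_spikes(train, p, rate_gain=1.0)
        actual = vc.power_spectrum(vc.simulate_vor(stimulus_120, p))
        sel = (pred.freqs >= 1.0) & (pred.freqs <= 15.0)
        ratio = np.mean(pred.power[sel]) / np.mean(actual.power[sel])
        assert ratio == pytest.approx(1.0, abs=0.25)

    def test_matching_index_higher_for_regular_neuron(self, stimulus_120):
        p = VORParams()
        actual = vc.power_spectrum(vc.simulate_vor(stimulus_120, p))
        mis = {}
        for cv in (0.1, 0.8):
            spec = vc.NeuronSpec(base_rate=50.0, target_cv=cv,
                                 sensitivity=0.5, kernel_shape="vor", seed=6,
                                 vor_params=p)
            train = vc.generate_ln_response(stimulus_120, spec)
            _, pred = vc.predict_eye_from_spikes(train, p, rate_gain=0.5)
            mis[cv] = vc.matching_index(pred, actual).mi
        assert mis[0.1] > mis[0.8]

    def test_resting_discharge_prediction_is_filtered_noise_floor(self):
        p = VORParams()
        train = vc.generate_renewal_spiketrain(50.0, 0.5, 120.0, seed=7)
        _, pred = vc.predict_eye_from_spikes(train, p, rate_gain=1.0)
        raw = vc.power_spectrum(train)
        sel = (pred.freqs >= 1.0) & (pred.freqs <= 20.0)
        gain2 = np.abs(ni_plant_response(p, pred.freqs[sel])) ** 2
        # spike spectra use the rate convention (one-sided density / 2)
        expected = raw.power[sel] * gain2 * 2.0
        assert np.mean(pred.power[sel]) == pytest.approx(
            np.mean(expected), rel=0.1)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vc.predict_eye_from_spikes(
                vc.SpikeTrain([], duration=10.0), VORParams())


class TestMatchingIndex:
    def grid(self):
        return np.linspace(0.5, 20.0, 40)

    def test_identical_spectra_score_one(self):
        f = self.grid()
        p = 1.0 + np.sin(f) ** 2
        a = vc.SpectralEstimate(f, p)
        b = vc.SpectralEstimate(f, p.copy())
        assert vc.matching_index(a, b).mi == 1.0

    def test_constant_log_offset_closed_form(self):
        f = self.grid()
        rng = np.random.default_rng(8)
        p = np.exp(rng.normal(0.0, 1.0, f.size))
        c = 3.0
        actual = vc.SpectralEstimate(f, p)
        pred = vc.SpectralEstimate(f, c * p)
        sd = np.std(np.log(p))
        expected = max(0.0, 1.0 - np.log(c) / sd)
        assert vc.matching_index(pred, actual).mi == pytest.approx(expected,
                                                                   rel=1e-9)

    def test_uncorrelated_spectra_score_near_zero(self):
        f = self.grid()
        rng = np.random.default_rng(9)
        a = vc.SpectralEstimate(f, np.exp(rng.normal(0, 2, f.size)))
        b = vc.SpectralEstimate(f, np.exp(rng.normal(0, 2, f.size)))
        assert vc.matching_index(a, b).mi < 0.2

    def test_invariant_to_common_rescaling(self):
        f = self.grid()
        rng = np.random.default_rng(10)
        p = np.exp(rng.normal(0, 1, f.size))
        q = np.exp(rng.normal(0, 1, f.size))
        base = vc.matching_index(vc.SpectralEstimate(f, p),
                                 vc.SpectralEstimate(f, q)).mi
        scaled = vc.matching_index(vc.SpectralEstimate(f, 7.0 * p),
                                   vc.SpectralEstimate(f, 7.0 * q)).mi
        assert scaled == pytest.approx(base, rel=1e-9)


class TestVorGain:
    def test_linear_relation_recovered(self):
        rng = np.random.default_rng(11)
        head = vc.Trace(rng.standard_normal(20000) * 30.0)
        eye = vc.Trace(-0.95 * head.values)
        gain, diag = vc.vor_gain(head, eye)
        assert gain == pytest.approx(0.95, rel=1e-9)
        assert diag["r_squared"] == pytest.approx(1.0)

    def test_excluded_transients_do_not_bias_the_fit(self):
        rng = np.random.default_rng(12)
        head = vc.Trace(rng.standard_normal(20000) * 30.0)
        eye_vals = -0.95 * head.values
        eye_vals[5000:5100] += 300.0
        eye_vals[12000:12080] -= 300.0
        mask = vc.SegmentMask([(5.0, 5.1), (12.0, 12.08)], label="saccade")
        gain, _ = vc.vor_gain(head, vc.Trace(eye_vals), exclude=mask)
        assert gain == pytest.approx(0.95, rel=1e-9)

    def test_too_little_retained_data_rejected(self):
        head = vc.Trace(np.random.default_rng(0).standard_normal(2000))
        eye = vc.Trace(-head.values)
        with pytest.raises(ValueError, match="retained"):
            vc.vor_gain(head, eye, exclude=vc.SegmentMask([(0.0, 1.5)]))
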