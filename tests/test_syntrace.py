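import math

import numpy as np
import pytest

from glyrfluct import syntrace as st


def ensemble_cfg(**overrides):
    base = dict(
        n_channels=200,
        unitary_current=2.0,
        k_open=50.0,
        k_close=50.0,
        baseline_noise_sd=0.0,
        sampling_rate=20000.0,
        duration=60.0,
        seed=1,
    )
    base.update(overrides)
    return st.ChannelSimConfig(**base)


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(st.ConfigurationError):
            ensemble_cfg(k_open=-1.0)

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(st.ConfigurationError):
            ensemble_cfg(k_close=math.inf)

    def test_undersampled_gating_rejected(self):
        with pytest.raises(st.ConfigurationError, match="resolvable"):
            ensemble_cfg(sampling_rate=100.0)

    def test_missing_seed_rejected(self):
        with pytest.raises(st.ConfigurationError, match="seed"):
            st.MipsTrainConfig(
                event_rate=1.0, amp_mean=10.0, amp_cv=0.1, tau_rise=0.5,
                tau_decay=5.0, baseline_noise_sd=1.0, duration=1.0,
            )

    def test_stationary_popen(self):
        assert ensemble_cfg(k_open=30.0, k_close=70.0).p_open_stationary == 0.3


class TestTwoStateEnsemble:
    def test_all_closed_when_k_open_zero(self):
        cfg = ensemble_cfg(k_open=0.0, baseline_noise_sd=3.0, duration=5.0)
        trace, _ = st.simulate_two_state_ensemble(cfg)
        assert abs(trace.samples.mean()) < 0.2
        assert trace.samples.var() == pytest.approx(9.0, rel=0.1)

    def test_all_open_when_k_close_zero(self):
        cfg = ensemble_cfg(k_close=0.0, duration=1.0, n_channels=30)
        trace, _ = st.simulate_two_state_ensemble(cfg)
        np.testing.assert_array_equal(trace.samples, -60.0)

    def test_binomial_moments(self):
        # analytic oracle: mean n*i*p = 200 pA, variance i^2*n*p*(1-p) = 200 pA^2
        cfg = ensemble_cfg()
        trace, gt = st.simulate_two_state_ensemble(cfg)
        assert -trace.samples.mean() == pytest.approx(200.0, rel=0.02)
        assert trace.samples.var() == pytest.approx(200.0, rel=0.10)
        assert gt.params["expected_mean_pa"] == pytest.approx(200.0)
        assert gt.params["expected_channel_variance_pa2"] == pytest.approx(200.0)

    def test_seed_reproducibility_bit_identical(self):
        cfg = ensemble_cfg(duration=2.0, baseline_noise_sd=1.0)
        t1, _ = st.simulate_two_state_ensemble(cfg)
        t2, _ = st.simulate_two_state_ensemble(cfg)
        np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_autocovariance_relaxation_time(self):
        # two-state autocovariance decays as exp(-(k_open+k_close)*lag)
        cfg = ensemble_cfg(
            n_channels=400, k_open=25.0, k_close=25.0, sampling_rate=2000.0,
            duration=40.0, seed=5,
        )
        trace, _ = st.simulate_two_state_ensemble(cfg)
        x = trace.samples - trace.samples.mean()
        n = x.size
        acf = np.correlate(x, x, mode="full")[n - 1:] / np.arange(n, 0, -1)
        acf /= acf[0]
        lags = np.arange(acf.size) / cfg.sampling_rate
        use = acf > 0.1
        use &= lags < 5.0 / (cfg.k_open + cfg.k_close)
        slope = np.polyfit(lags[use], np.log(acf[use]), 1)[0]
        assert -1.0 / slope == pytest.approx(1.0 / 50.0, rel=0.15)


class TestGlycineApplication:
    def test_zero_profile_is_baseline_only(self):
        cfg = ensemble_cfg(duration=2.0, baseline_noise_sd=1.0)
        trace, _ = st.simulate_glycine_application(cfg, lambda t: 0.0)
        assert abs(trace.samples.mean()) < 0.1
        assert trace.samples.var() == pytest.approx(1.0, rel=0.2)

    def test_profile_out_of_range_rejected(self):
        cfg = ensemble_cfg(duration=1.0)
        with pytest.raises(st.ConfigurationError):
            st.simulate_glycine_application(cfg, lambda t: 1.5)

    def test_constant_profile_matches_stationary_ensemble_moments(self):
        # matched-moment comparison over 20 seeds: tracking a flat profile at
        # the stationary open probability must be statistically the same
        means_a, means_b, vars_a, vars_b = [], [], [], []
        for seed in range(20):
            cfg = ensemble_cfg(n_channels=50, duration=3.0, seed=seed)
            ta, _ = st.simulate_two_state_ensemble(cfg)
            tb, _ = st.simulate_glycine_application(
                cfg, lambda t: cfg.p_open_stationary
            )
            means_a.append(ta.samples.mean())
            means_b.append(tb.samples.mean())
            vars_a.append(ta.samples.var())
            vars_b.append(tb.samples.var())
        assert np.mean(means_b) == pytest.approx(np.mean(means_a), rel=0.03)
        assert np.mean(vars_b) == pytest.approx(np.mean(vars_a), rel=0.15)

    def test_triangular_profile_lead_in_and_peak(self):
        prof = st.triangular_profile(0.9, 60.0, lead_in=5.0)
        assert prof(0.0) == 0.0
        assert prof(5.0) == 0.0
        assert prof(32.5) == pytest.approx(0.9)
        assert prof(60.0) == pytest.approx(0.0)


class TestMipscTrain:
    def train_cfg(self, **overrides):
        base = dict(
            event_rate=1.0, amp_mean=50.0, amp_cv=0.3, tau_rise=0.5,
            tau_decay=5.0, baseline_noise_sd=2.0, duration=10.0,
            sampling_rate=20000.0, seed=3,
        )
        base.update(overrides)
        return st.MipsTrainConfig(**base)

    def test_tau_order_enforced(self):
        with pytest.raises(st.ConfigurationError):
            self.train_cfg(tau_rise=5.0, tau_decay=0.5)

    def test_zero_rate_gives_pure_noise(self):
        trace, gt = st.simulate_mipsc_train(self.train_cfg(event_rate=0.0))
        assert gt.event_onsets == []
        assert trace.samples.std() == pytest.approx(2.0, rel=0.1)

    def test_single_event_peak_amplitude_and_time(self):
        # analytic oracle: peak at t* = tr*td/(td-tr)*ln(td/tr)
        cfg = self.train_cfg(
            event_rate=0.1, baseline_noise_sd=0.0, amp_cv=0.0, amp_mean=50.0,
            duration=10.0, seed=6,
        )
        trace, gt = st.simulate_mipsc_train(cfg)
        assert len(gt.event_onsets) == 1
        t_star_ms = st.biexp_peak_time(0.5, 5.0)
        assert t_star_ms == pytest.approx(0.5 * 5.0 / 4.5 * math.log(10.0))
        peak_idx = np.argmin(trace.samples)
        onset = gt.event_onsets[0]
        assert -trace.samples[peak_idx] == pytest.approx(50.0, rel=0.01)
        assert peak_idx / cfg.sampling_rate - onset == pytest.approx(
            t_star_ms * 1e-3, abs=1.5 / cfg.sampling_rate
        )

    def test_poisson_event_count(self):
        cfg = self.train_cfg(duration=300.0, sampling_rate=2000.0, seed=21)
        _, gt = st.simulate_mipsc_train(cfg)
        assert abs(len(gt.event_onsets) - 300) <= 3 * math.sqrt(300)

    def test_ground_truth_reconstructs_noiseless_trace(self):
        cfg = self.train_cfg(baseline_noise_sd=0.0, duration=5.0, seed=9)
        trace, gt = st.simulate_mipsc_train(cfg)
        rebuilt = np.zeros(trace.n_samples)
        kernel_n = int(round(8.0 * cfg.tau_decay * 1e-3 * cfg.sampling_rate))
        for onset, amp in zip(gt.event_onsets, gt.event_amplitudes):
            i0 = int(math.ceil(onset * cfg.sampling_rate - 1e-9))
            i1 = min(i0 + kernel_n, trace.n_samples)
            t_ms = (np.arange(i0, i1) / cfg.sampling_rate - onset) * 1e3
            rebuilt[i0:i1] -= st.biexp_waveform(t_ms, amp, 0.5, 5.0)
        np.testing.assert_allclose(rebuilt, trace.samples, atol=1e-12)

    def test_amplitude_distribution_matches_config(self):
        cfg = self.train_cfg(duration=600.0, event_rate=2.0,
                             sampling_rate=2000.0, tau_decay=5.0, seed=17)
        _, gt = st.simulate_mipsc_train(cfg)
        amps = np.array(gt.event_amplitudes)
        assert amps.mean() == pytest.approx(50.0, rel=0.05)
        assert amps.std() / amps.mean() == pytest.approx(0.3, rel=0.15)
        assert np.all(amps > 0)


class TestDoseResponse:
    def test_half_maximum_at_ec50(self):
        table = st.simulate_dose_response(300.0, 1.5, 1000.0, [300.0], 0.0, 1, 0)
        assert table["peak_pa"].iloc[0] == pytest.approx(500.0)

    def test_saturation(self):
        table = st.simulate_dose_response(300.0, 1.0, 1000.0, [3e8], 0.0, 1, 0)
        assert table["peak_pa"].iloc[0] == pytest.approx(1000.0, abs=1e-4 * 1000)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(st.ConfigurationError):
            st.simulate_dose_response(300.0, 1.5, 1000.0, [], 0.0, 1, 0)

    def test_table_shape(self):
        table = st.simulate_dose_response(
            300.0, 1.5, 1000.0, [10, 100, 1000], 0.08, 5, 4
        )
        assert len(table) == 15
        assert set(table.columns) == {"cell_id", "concentration_um", "peak_pa"}


class TestTonicBlock:
    def tonic_cfg(self, **overrides):
        base = dict(
            n_channels=50, unitary_current=2.0, k_open=60.0, k_close=60.0,
            baseline_noise_sd=2.0, sampling_rate=5000.0, duration=45.0, seed=9,
        )
        base.update(overrides)
        return st.ChannelSimConfig(**base)

    def test_block_onset_outside_trace_rejected(self):
        with pytest.raises(st.ConfigurationError):
            st.simulate_tonic_block(self.tonic_cfg(), 100.0)

    def test_no_channels_no_change(self):
        trace, _ = st.simulate_tonic_block(self.tonic_cfg(n_channels=0), 30.0)
        pre = trace.samples[: trace.index_of(30.0)]
        post = trace.samples[trace.index_of(30.0):]
        assert abs(pre.mean() - post.mean()) < 0.2

    def test_binomial_shift_oracle(self):
        # oracle: holding shift n*i*p = 50 pA, variance shift i^2*n*p*(1-p) = 50
        trace, gt = st.simulate_tonic_block(self.tonic_cfg(), 30.0)
        i_b = trace.index_of(30.0)
        pre = trace.samples[trace.index_of(10.0): i_b]
        post = trace.samples[trace.index_of(35.0):]
        assert abs(pre.mean() - post.mean()) == pytest.approx(50.0, rel=0.05)
        assert pre.var() - post.var() == pytest.approx(50.0, rel=0.25)
        assert gt.params["expected_variance_shift_pa2"] == pytest.approx(50.0)

    def test_annotation_attached(self):
        trace, _ = st.simulate_tonic_block(self.tonic_cfg(), 30.0)
        ann = trace.find_annotation("strychnine")
        assert ann.onset == 30.0

    def test_frozen_closed_zero_trace(self):
        cfg = self.tonic_cfg(
            k_open=0.0, k_close=0.0, baseline_noise_sd=0.0, duration=10.0,
            sampling_rate=1000.0,
        )
        trace, _ = st.simulate_tonic_block(cfg, 5.0)
        np.testing.assert_array_equal(trace.samples, 0.0)
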