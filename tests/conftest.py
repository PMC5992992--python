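import numpy as np
import pytest

from glyrfluct import syntrace as st


@pytest.fixture(scope="session")
def reference_ramp():
    """One realization of the reference agonist-ramp simulation
    (100 channels, 2 pA unitary current, peak open probability 0.9)."""
    cfg = st.ChannelSimConfig(
        n_channels=100,
        unitary_current=2.0,
        k_open=200.0,
        k_close=200.0,
        baseline_noise_sd=2.0,
        sampling_rate=20000.0,
        duration=60.0,
        seed=42,
    )
    profile = st.triangular_profile(0.9, cfg.duration, lead_in=5.0)
    trace, gt = st.simulate_glycine_application(cfg, profile)
    return cfg, trace, gt


@pytest.fixture(scope="session")
def mipsc_train_10sigma():
    """60 s mIPSC train with amplitude 10x the 3 pA baseline noise."""
    cfg = st.MipsTrainConfig(
        event_rate=1.0,
        amp_mean=30.0,
        amp_cv=0.0,
        tau_rise=0.5,
        tau_decay=5.0,
        baseline_noise_sd=3.0,
        duration=60.0,
        sampling_rate=10000.0,
        seed=7,
    )
    trace, gt = st.simulate_mipsc_train(cfg)
    return cfg, trace, gt


def crossing_times_dense(amplitude, tau_rise_ms, tau_decay_ms, dt_us=1.0):
    """Independent dense-grid oracle for 10-90% rise and 90-10% decay (ms)."""
    t = np.arange(0.0, 12.0 * tau_decay_ms, dt_us * 1e-3)
    w = st.biexp_waveform(t, amplitude, tau_rise_ms, tau_decay_ms)
    pk = int(np.argmax(w))
    peak = w[pk]

    def first_cross(y, tt, level, rising):
        idx = np.flatnonzero(y >= level if rising else y <= level)
        return tt[idx[0]]

    t10 = first_cross(w[: pk + 1], t[: pk + 1], 0.1 * peak, True)
    t90 = first_cross(w[: pk + 1], t[: pk + 1], 0.9 * peak, True)
    d90 = first_cross(w[pk:], t[pk:], 0.9 * peak, False)
    d10 = first_cross(w[pk:], t[pk:], 0.1 * peak, False)
    return t90 - t10, d10 - d90
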