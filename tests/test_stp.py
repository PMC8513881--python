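"""Short-term plasticity core: exact updates, steady states, conversions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ca3mod.stp import (AmplitudeTrain, ConfigurationError, ModelSpec,
                        RecordingConfig, STPParams, StimulusTrain,
                        amplitude_to_current, burst_response, iterate_stp,
                        steady_state)

EPSC = STPParams(g_max=6.6, tau_f=3.3, f0=0.3, a=0.15)
IPSC = STPParams(g_max=26.0, tau_f=1.4, f0=0.05, tau_d=0.8,
                 tau_a=8.0, a0=0.08, b_a=0.11)
F2 = ModelSpec.preset("f2")
AFD = ModelSpec.preset("afd")


def ode_amplitudes(params, spec, times):
    """Independent oracle: stiff integration of the continuous dynamics
    with delta increments applied at each stimulus."""
    f = params.f0
    d = 1.0
    a = params.a0 if spec.a_dynamic else params.a
    amps = []
    for i, t in enumerate(times):
        amps.append(f ** spec.f_exponent * d)
        fp = f + a * (1 - f)
        dp = d * (1 - f) if spec.d_active else 1.0
        ap = a + params.b_a * (1 - a) if spec.a_dynamic else a
        if i == len(times) - 1:
            break
        span = times[i + 1] - t

        def rhs(_, y):
            return [(params.f0 - y[0]) / params.tau_f,
                    (1 - y[1]) / params.tau_d if spec.d_active else 0.0,
                    (params.a0 - y[2]) / params.tau_a if spec.a_dynamic else 0.0]

        sol = solve_ivp(rhs, (0, span), [fp, dp, ap], method="LSODA",
                        rtol=1e-10, atol=1e-12)
        f, d, a = sol.y[:, -1]
        if not spec.d_active:
            d = 1.0
    return np.array(amps)


class TestIterate:
    def test_zero_increment_gives_constant_train(self):
        p = EPSC.updated(a=0.0)
        traj = iterate_stp(p, F2, StimulusTrain([0.0, 0.01, 0.5, 3.0]))
        assert np.allclose(traj.amplitudes, 0.3 ** 2)

    def test_two_pulse_ratio_matches_hand_substitution(self):
        # f2 after one 50 ms ISI: f0 - (f0 - f+) exp(-dt/tau_f)
        traj = iterate_stp(EPSC, F2, StimulusTrain([0.0, 0.05]))
        fplus = 0.3 + 0.15 * 0.7
        f2 = 0.3 - (0.3 - fplus) * np.exp(-0.05 / 3.3)
        assert traj.amplitudes[1] / traj.amplitudes[0] == pytest.approx(
            (f2 / 0.3) ** 2, rel=1e-12)

    @pytest.mark.parametrize("params,spec", [
        (EPSC, F2), (IPSC, AFD),
        (STPParams(tau_f=1.0, f0=0.2, a=0.1, tau_d=0.5), ModelSpec.preset("fd")),
    ])
    def test_matches_ode_integration(self, params, spec):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 30, 40))
        traj = iterate_stp(params, spec, StimulusTrain(times))
        oracle = ode_amplitudes(params, spec, times)
        assert np.max(np.abs(traj.amplitudes - oracle) / oracle) < 1e-6

    def test_state_boundedness_random_sweep(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = STPParams(tau_f=rng.uniform(0.02, 10), f0=rng.uniform(0, 1),
                          tau_d=rng.uniform(0.02, 10),
                          tau_a=rng.uniform(0.02, 10), a0=rng.uniform(0, 1),
                          b_a=rng.uniform(0, 1))
            times = np.cumsum(rng.exponential(0.3, 100))
            traj = iterate_stp(p, AFD, StimulusTrain(times))
            for arr in (traj.f, traj.d, traj.a, traj.f0):
                assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_monotone_in_facilitation_increment(self):
        times = StimulusTrain(np.arange(20) * 0.1)
        lo = iterate_stp(EPSC.updated(a=0.1), F2, times).amplitudes
        hi = iterate_stp(EPSC.updated(a=0.3), F2, times).amplitudes
        assert np.all(hi[1:] >= lo[1:])

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            StimulusTrain([0.0, 0.1, 0.1])
        with pytest.raises(ValueError):
            StimulusTrain([-1.0, 0.1])
        with pytest.raises(ConfigurationError):
            iterate_stp(STPParams(tau_f=1.0), F2, StimulusTrain([0.0]))
        with pytest.raises(ValueError):
            AmplitudeTrain([0.0, 1.0], [1.0])


class TestSteadyState:
    def test_long_interval_limit_recovers_baselines(self):
        a, f, d = steady_state(IPSC, 1e9, AFD)
        assert (a, f, d) == pytest.approx((0.08, 0.05, 1.0), abs=1e-9)

    def test_short_interval_limit(self):
        a, f, d = steady_state(IPSC, 1e-12, AFD)
        assert f == pytest.approx(1.0, abs=1e-6)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_matches_long_train_iteration(self):
        a_inf, f_inf, d_inf = steady_state(IPSC, 2.0, AFD)
        times = np.arange(3000) * 2.0
        traj = iterate_stp(IPSC, AFD, StimulusTrain(times))
        assert a_inf == pytest.approx(traj.a[-1], abs=1e-8)
        assert f_inf == pytest.approx(traj.f[-1], abs=1e-8)
        assert d_inf == pytest.approx(traj.d[-1], abs=1e-8)

    def test_rejects_nonpositive_interval(self):
        with pytest.raises(ValueError):
            steady_state(IPSC, 0.0, AFD)


class TestBurstResponse:
    def test_single_pulse_is_steady_state_amplitude(self):
        a_inf, f_inf, d_inf = steady_state(IPSC, 2.0, AFD)
        amp = burst_response(IPSC, AFD, 2.0, 0.02, 1).amplitudes
        assert amp[0] == pytest.approx(f_inf * d_inf, rel=1e-12)

    @pytest.mark.parametrize("params,spec", [(EPSC, F2), (IPSC, AFD)])
    def test_matches_embedded_burst_in_long_train(self, params, spec):
        dt_between, dt_within, n = 2.0, 0.02, 10
        burst = burst_response(params, spec, dt_between, dt_within, n)
        background = np.arange(4000) * dt_between
        embedded = np.concatenate([background,
                                   background[-1] + dt_between
                                   + np.arange(n) * dt_within])
        traj = iterate_stp(params, spec, StimulusTrain(embedded))
        full = traj.amplitudes[-n:]
        ratio = burst.amplitudes / burst.amplitudes[0]
        ratio_full = full / full[0]
        assert np.max(np.abs(ratio - ratio_full)) < 1e-6

    def test_frequency_facilitation_saturates_with_short_intervals(self):
        # within-burst facilitation (2nd/1st) shrinks as the between-burst
        # interval shortens, because background spiking pre-facilitates f
        ratios = []
        for bi in (60.0, 5.0, 0.5):
            amps = burst_response(EPSC, F2, bi, 0.05, 2).amplitudes
            ratios.append(amps[1] / amps[0])
        assert ratios[0] > ratios[1] > ratios[2]


class TestAmplitudeToCurrent:
    def test_zero_driving_force_and_zero_amplitude(self):
        rec = RecordingConfig(v_mem=10.0, e_glut=10.0, e_gaba=-70.0)
        assert amplitude_to_current(0.5, EPSC, rec, "excitatory") == 0.0
        rec2 = RecordingConfig(v_mem=-70.0)
        assert amplitude_to_current(0.0, EPSC, rec2, "excitatory") == 0.0

    def test_hand_arithmetic(self):
        rec = RecordingConfig(v_mem=-70.0, e_glut=0.0, e_gaba=-75.0)
        i = amplitude_to_current(0.09, EPSC, rec, "excitatory")
        assert i == pytest.approx(6.6 * 0.09 * -70.0)

    def test_rejects_unknown_pathway(self):
        with pytest.raises(ValueError):
            amplitude_to_current(0.1, EPSC, RecordingConfig(), "modulatory")
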