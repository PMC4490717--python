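"""Rate filter and control laws: frozen hand-computed values, fixed points,
anti-windup, pulse-rate cap, and equivalence with a literal transcription of
the published update equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optoclamp.controllers import (
    IntegralConfig,
    OnOffState,
    PIConfig,
    PIState,
    RateEstimate,
    RateFilterConfig,
    TargetSchedule,
    compute_alpha,
    integral_step,
    onoff_excitatory_step,
    onoff_inhibitory_step,
    pi_step,
    split_control,
    update_rate_estimate,
)


class TestRateFilter:
    @pytest.mark.parametrize(
        "dt,tau,expected",
        [(0.004, 2.5, 1.5987e-3), (0.004, 0.8, 4.9875e-3)],
    )
    def test_alpha_values(self, dt, tau, expected):
        assert compute_alpha(dt, tau) == pytest.approx(expected, abs=1e-7)

    def test_alpha_limit_and_monotonicity(self):
        assert compute_alpha(0.004, 1e9) == pytest.approx(0.0, abs=1e-8)
        assert compute_alpha(0.008, 2.5) > compute_alpha(0.004, 2.5)
        assert compute_alpha(0.004, 5.0) < compute_alpha(0.004, 2.5)

    @pytest.mark.parametrize("dt,tau", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_alpha_rejects_nonpositive(self, dt, tau):
        with pytest.raises(ValueError):
            compute_alpha(dt, tau)

    def test_config_rejects_inconsistent_alpha(self):
        with pytest.raises(ValueError):
            RateFilterConfig(dt=0.004, tau=2.5, alpha=0.5)

    def test_update_hand_value(self):
        # alpha = 0.0016 exactly; tau chosen to match the invariant
        alpha = 0.0016
        tau = -0.004 / math.log(1.0 - alpha)
        cfg = RateFilterConfig(dt=0.004, tau=tau, n_units=10, alpha=alpha)
        state = update_rate_estimate(RateEstimate(f=1.0), cfg, n_spikes=2)
        assert state.r_inst == pytest.approx(50.0)
        assert state.f == pytest.approx(1.0784, abs=1e-6)

    def test_update_rejects_negative_count(self):
        cfg = RateFilterConfig(dt=0.004, tau=2.5, n_units=10)
        with pytest.raises(ValueError):
            update_rate_estimate(RateEstimate(), cfg, n_spikes=-1)

    def test_decay_and_steady_state(self):
        cfg = RateFilterConfig(dt=0.004, tau=2.5, n_units=10)
        state = RateEstimate(f=7.0)
        n_steps = int(20 * cfg.tau / cfg.dt)
        for _ in range(n_steps):
            state = update_rate_estimate(state, cfg, 0)
        assert state.f < 1e-6
        # constant input converges to the constant
        c_spikes = 2  # r_inst = 50 Hz/unit
        for _ in range(n_steps):
            state = update_rate_estimate(state, cfg, c_spikes)
        assert abs(state.f - 50.0) < 1e-6 * 50.0

    def test_step_response_time_constant(self):
        cfg = RateFilterConfig(dt=0.004, tau=2.5, n_units=1)
        state = RateEstimate(f=0.0)
        target = 1.0 / (1.0 * cfg.dt)  # one spike per bin => constant r_inst
        t, crossed = 0.0, None
        for _ in range(int(5 * cfg.tau / cfg.dt)):
            state = update_rate_estimate(state, cfg, 1)
            t += cfg.dt
            if crossed is None and state.f >= (1 - 1 / math.e) * target:
                crossed = t
        assert crossed == pytest.approx(cfg.tau, abs=cfg.dt * 1.001)


class TestTargetSchedule:
    def test_piecewise_lookup(self):
        sched = TargetSchedule(segments=[(0.0, 2.0), (10.0, 5.0)])
        assert sched.target_at(-1.0) == 2.0
        assert sched.target_at(9.999) == 2.0
        assert sched.target_at(10.0) == 5.0

    def test_invalid_schedules(self):
        with pytest.raises(ValueError):
            TargetSchedule(segments=[])
        with pytest.raises(ValueError):
            TargetSchedule(segments=[(0, 1), (0, 2)])
        with pytest.raises(ValueError):
            TargetSchedule(segments=[(0, -1)])


class TestPI:
    def test_zero_error_fixed_point(self):
        cfg = PIConfig()
        state = PIState(u=0.3, e_prev=0.0)
        for _ in range(100):
            state = pi_step(state, cfg, 0.0)
        assert state.u == 0.3

    def test_hand_value(self):
        cfg = PIConfig(K=0.1, Ti=1.0, Ts=0.01)
        state = pi_step(PIState(u=0.2, e_prev=0.5), cfg, e=0.3)
        assert state.u == pytest.approx(0.1803, abs=1e-12)
        assert state.e_prev == 0.3

    def test_windup_bound_under_persistent_error(self):
        cfg = PIConfig()
        state = PIState()
        for _ in range(10_000):
            state = pi_step(state, cfg, 10.0)
            u_c, u_h = split_control(state.u, cfg)
            assert 0.0 <= u_c <= 1.0 and 0.0 <= u_h <= 1.0
        assert state.u == pytest.approx(cfg.u_hi)

    def test_rejects_nonfinite_error(self):
        with pytest.raises(ValueError):
            pi_step(PIState(), PIConfig(), float("nan"))

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=300))
    @settings(deadline=None, max_examples=50)
    def test_anti_windup_any_bounded_error_sequence(self, errors):
        cfg = PIConfig()
        state = PIState()
        for e in errors:
            state = pi_step(state, cfg, e)
            u_c, u_h = split_control(state.u, cfg)
            assert 0.0 <= u_c <= 1.0
            assert 0.0 <= u_h <= 1.0


class TestSplit:
    def test_neutral_point(self):
        assert split_control(0.0, PIConfig()) == (0.25, 0.25)

    def test_clipping(self):
        assert split_control(0.9, PIConfig()) == (1.0, 0.0)
        assert split_control(-0.9, PIConfig()) == (0.0, 1.0)

    @given(st.floats(-0.25, 0.25))  # range where neither output clips
    @settings(deadline=None, max_examples=50)
    def test_unclipped_sum_is_offset_sum(self, u):
        cfg = PIConfig()
        u_c, u_h = split_control(u, cfg)
        assert u_c + u_h == pytest.approx(cfg.delta1 + cfg.delta2, abs=1e-12)


class TestIntegral:
    def test_zero_error_and_increment(self):
        cfg = IntegralConfig(Ti=1.0, Ts=0.01)
        state = PIState(u=0.5)
        assert integral_step(state, cfg, 0.0).u == 0.5
        state = PIState()
        for k in range(1, 40):
            state = integral_step(state, cfg, 2.0)
            assert state.u == pytest.approx(min(1.0, 0.02 * k), abs=1e-12)
        assert state.u == pytest.approx(0.78, abs=1e-12)  # still climbing

    def test_lower_clip(self):
        state = integral_step(PIState(u=0.0), IntegralConfig(), -100.0)
        assert state.u == 0.0


class TestOnOff:
    def test_excitatory_silent_without_positive_error(self):
        state = OnOffState(mode="excitatory")
        t = 0.0
        for _ in range(1000):
            state, pulse = onoff_excitatory_step(state, -0.5, 0.004, t)
            assert pulse is None
            t += 0.004

    def test_excitatory_pulse_rate_capped_at_10hz(self):
        state = OnOffState(mode="excitatory")
        onsets = []
        t = 0.0
        for _ in range(2500):  # 10 s at the 4 ms filter rate
            state, pulse = onoff_excitatory_step(state, 1.0, 0.004, t)
            if pulse is not None:
                onsets.append(pulse.t)
                assert pulse.width_ms == 5.0
                assert pulse.power == pytest.approx(13.4)
            t += 0.004
        gaps = np.diff(onsets)
        assert np.allclose(gaps, 0.1, atol=1e-9)  # exactly 10 Hz
        assert len(onsets) == pytest.approx(100, abs=1)

    def test_excitatory_stops_when_integral_goes_negative(self):
        state = OnOffState(mode="excitatory")
        t = 0.0
        state, pulse = onoff_excitatory_step(state, 5.0, 0.004, t)
        assert pulse is not None
        for _ in range(200):
            t += 0.004
            state, pulse = onoff_excitatory_step(state, -10.0, 0.004, t)
        assert state.I_f < 0
        assert pulse is None

    def test_inhibitory_gating(self):
        state = OnOffState(mode="inhibitory")
        for _ in range(100):
            state, on = onoff_inhibitory_step(state, 0.5, 0.004)
            assert not on
        state, on = onoff_inhibitory_step(state, -1000.0, 0.004)
        assert on
        # constant negative error keeps the light on
        for _ in range(100):
            state, on = onoff_inhibitory_step(state, -1.0, 0.004)
            assert on

    def test_inhibitory_duty_follows_sign_of_running_sum(self, rng):
        errors = rng.normal(0.0, 1.0, 500)
        state = OnOffState(mode="inhibitory", i_bound=1e9)
        acc = 0.0
        for e in errors:
            state, on = onoff_inhibitory_step(state, e, 0.004)
            acc += e * 0.004
            assert on == (acc < 0)

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            onoff_excitatory_step(OnOffState(mode="inhibitory"), 1.0, 0.004, 0.0)
        with pytest.raises(ValueError):
            onoff_inhibitory_step(OnOffState(mode="excitatory"), 1.0, 0.004)


class TestLiteralTranscription:
    """100-step trajectories must match an independently coded, literal
    transcription of the published update equations to 1e-12."""

    def test_filter_pi_split_trajectory(self, rng):
        dt, tau, n_units = 0.004, 2.5, 10
        K, Ti, Ts, d1, d2 = 0.1, 1.0, 0.01, 0.25, 0.25
        spike_counts = rng.poisson(0.8, 100)
        f_star = 4.0

        # literal transcription, coded independently of the package types
        alpha = 1 - math.exp(-dt / tau)
        f, u, e_prev = 0.0, 0.0, 0.0
        oracle = []
        for n in spike_counts:
            r = n / (n_units * dt)
            f = alpha * r + (1 - alpha) * f
            e = f_star - f
            u = u + K * (e - e_prev + (Ts / Ti) * e)
            u = min(max(u, -(1 - d2)), 1 - d1)  # keep both outputs in [0, 1]
            e_prev = e
            uc = min(max(u + d1, 0.0), 1.0)
            uh = min(max(-u + d2, 0.0), 1.0)
            oracle.append((f, u, uc, uh))

        fcfg = RateFilterConfig(dt=dt, tau=tau, n_units=n_units)
        pcfg = PIConfig(K=K, Ti=Ti, Ts=Ts, delta1=d1, delta2=d2)
        est, pi = RateEstimate(), PIState()
        for n, (f_o, u_o, uc_o, uh_o) in zip(spike_counts, oracle):
            est = update_rate_estimate(est, fcfg, int(n))
            pi = pi_step(pi, pcfg, f_star - est.f)
            uc, uh = split_control(pi.u, pcfg)
            assert abs(est.f - f_o) < 1e-12
            assert abs(pi.u - u_o) < 1e-12
            assert abs(uc - uc_o) < 1e-12 and abs(uh - uh_o) < 1e-12

    def test_integral_trajectory(self, rng):
        Ti, Ts = 1.0, 0.01
        errors = rng.normal(0, 5, 100)
        u = 0.0
        cfg = IntegralConfig(Ti=Ti, Ts=Ts)
        state = PIState()
        for e in errors:
            u = min(max(u + (Ts / Ti) * e, 0.0), 1.0)
            state = integral_step(state, cfg, e)
            assert abs(state.u - u) < 1e-12

    def test_onoff_trajectory(self, rng):
        errors = rng.normal(0, 2, 100)
        dt = 0.004
        I_f, t_last = 0.0, -1e18
        state = OnOffState(mode="excitatory")
        t = 0.0
        for e in errors:
            I_f = min(max(I_f + e * dt, -10.0), 10.0)
            fire = I_f > 0 and t - t_last >= 0.1 - 1e-9
            if fire:
                t_last = t
            state, pulse = onoff_excitatory_step(state, e, dt, t)
            assert abs(state.I_f - I_f) < 1e-12
            assert (pulse is not None) == fire
            t += dt
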