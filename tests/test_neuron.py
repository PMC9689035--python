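"""Unit dynamics: ion-channel current, gating, firing, reset, surrogate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgcsnn.neuron import (
    NeuronParams, MembraneState, SpikeTrain, ion_channel_current,
    update_gating, fire_and_reset, rgc_step, lif_step, surrogate_grad,
)


def make_state(u=0.0, m=1.0, n=0.5, h=1.0, spike=0.0, shape=()):
    return MembraneState(
        u=np.full(shape, u), m=np.full(shape, m), n=np.full(shape, n),
        h=np.full(shape, h), last_spike=np.full(shape, spike))


class TestIonChannelCurrent:
    def test_zero_driving_force(self):
        p = NeuronParams(g_na=1.0, g_k=1.0, g_l=1.0, e_na=0.3, e_k=0.3, e_l=0.3)
        st_ = make_state(u=0.3, m=0.7, n=0.2, h=0.9)
        assert ion_channel_current(st_, p) == pytest.approx(0.0)

    def test_zero_conductance(self):
        p = NeuronParams(g_na=0.0, g_k=0.0, g_l=0.0)
        assert ion_channel_current(make_state(u=5.0), p) == pytest.approx(0.0)

    def test_hand_evaluated_sum(self):
        # g=1 for all channels, E*=0, U=1, gates fully open: 1+1+1
        p = NeuronParams(g_na=1.0, g_k=1.0, g_l=1.0, e_na=0.0, e_k=0.0, e_l=0.0)
        st_ = make_state(u=1.0, m=1.0, n=1.0, h=1.0)
        assert ion_channel_current(st_, p) == pytest.approx(3.0)

    def test_non_finite_state_rejected(self):
        p = NeuronParams()
        with pytest.raises(ValueError):
            ion_channel_current(make_state(u=np.nan), p)


class TestGating:
    def test_zero_rate_is_fixed_point(self):
        p = NeuronParams(gating_rate=0.0)
        st_ = make_state(u=0.7, m=0.3, n=0.4, h=0.8)
        out = update_gating(st_, p)
        assert out.m == st_.m and out.n == st_.n and out.h == st_.h

    def test_steady_state_at_current_value_unchanged(self):
        # At u = gate_mid the activation steady state is exactly 1/2;
        # gates already at 1/2 stay put for any rate.
        p = NeuronParams(gating_rate=0.7, gate_mid=0.25)
        st_ = make_state(u=0.25, m=0.5, n=0.5, h=0.5)
        out = update_gating(st_, p)
        assert out.m == pytest.approx(0.5)
        assert out.n == pytest.approx(0.5)
        assert out.h == pytest.approx(0.5)

    def test_single_euler_step(self):
        # from 0 toward steady state 1 with r*dt = 0.25 -> 0.25
        p = NeuronParams(gating_rate=0.25, gate_mid=0.25, gate_slope=0.1)
        st_ = make_state(u=100.0, m=0.0, n=0.0)  # act(100) ~= 1
        out = update_gating(st_, p)
        assert out.m == pytest.approx(0.25, abs=1e-9)
        assert out.n == pytest.approx(0.25, abs=1e-9)

    @given(u=st.floats(-5, 5), rate=st.floats(0, 4), m=st.floats(0, 1),
           n=st.floats(0, 1), h=st.floats(0, 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_gates_stay_in_unit_interval(self, u, rate, m, n, h):
        p = NeuronParams(gating_rate=rate)
        out = update_gating(make_state(u=u, m=m, n=n, h=h), p)
        for g in (out.m, out.n, out.h):
            assert 0.0 <= g <= 1.0


class TestFireAndReset:
    @pytest.mark.parametrize("u, want_spike, want_u", [
        (0.6, 1.0, 0.1),     # above threshold: spike, soft reset
        (0.4, 0.0, 0.4),     # below threshold: unchanged
        (0.5, 0.0, 0.5),     # equality: no spike (strict inequality)
    ])
    def test_threshold_cases(self, u, want_spike, want_u):
        spikes, u_after = fire_and_reset(np.asarray(u), NeuronParams())
        assert spikes == want_spike
        assert u_after == pytest.approx(want_u)

    @given(st.lists(st.floats(-2, 2), min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_soft_reset_conservation(self, us):
        u = np.asarray(us)
        spikes, u_after = fire_and_reset(u, NeuronParams())
        assert np.allclose(u - u_after, spikes * 0.5)
        assert set(np.unique(spikes)) <= {0.0, 1.0}


def iterate_rgc(current, n_steps, params=None, shape=()):
    p = params or NeuronParams(g_l=0.0)
    state = MembraneState.zeros(shape)
    spikes = []
    for _ in range(n_steps):
        state, s = rgc_step(state, np.full(shape, current), p)
        spikes.append(float(s))
    return spikes


class TestRGCStep:
    def test_zero_input_fixed_point(self):
        assert iterate_rgc(0.0, 8) == [0.0] * 8

    def test_hand_iterated_trajectory(self):
        # U (pre-reset, carrying -spike*Vth): 0.3, 0.6*, 0.4, 0.7*, 0.5,
        # 0.8*, 0.6*, 0.4 -> spikes at steps 2, 4, 6, 7 (strict U > 0.5)
        assert iterate_rgc(0.3, 8) == [0, 1, 0, 1, 0, 1, 1, 0]

    @pytest.mark.parametrize("c", [0.09, 0.17, 0.23, 0.41, 0.47])
    def test_closed_form_spike_times(self, c):
        # With zero conductance and sub-threshold drive (at most one
        # threshold multiple crossed per step) the k-th spike lands at
        # t = floor(k*Vth/c) + 1.  Currents keep >= 0.01 clearance from
        # exact crossings so float accumulation cannot flip a step.
        T = 40
        got = [t + 1 for t, s in enumerate(iterate_rgc(c, T)) if s]
        want = []
        k = 1
        while True:
            t = int(np.floor(k * 0.5 / c)) + 1
            if t > T:
                break
            want.append(t)
            k += 1
        assert got == want

    def test_supra_threshold_drive_fires_every_step(self):
        # input > Vth: one (binary) spike per step while the soft-reset
        # membrane keeps climbing by c - Vth each step
        assert iterate_rgc(0.77, 10) == [1.0] * 10

    def test_spikes_are_exactly_threshold_crossings(self):
        p = NeuronParams(g_l=0.1)
        state = MembraneState.zeros(())
        rng = np.random.default_rng(0)
        for _ in range(50):
            state, s = rgc_step(state, rng.uniform(0, 0.6), p)
            assert float(s) == (1.0 if state.u > p.v_th else 0.0)

    def test_shape_mismatch_rejected(self):
        state = MembraneState.zeros((3,))
        with pytest.raises(ValueError):
            rgc_step(state, np.zeros((4,)), NeuronParams())


class TestLIFStep:
    def test_no_decay_constant_membrane(self):
        p = NeuronParams(mode="lif", lif_decay=1.0)
        state = make_state(u=0.3)
        state, _ = lif_step(state, np.asarray(0.0), p)
        assert state.u == pytest.approx(0.3)

    def test_hand_iterated_trajectory(self):
        # decay 0.5, input 0.4: U = 0.4, 0.6*, 0.4, 0.6*, ...
        p = NeuronParams(mode="lif", lif_decay=0.5)
        state = MembraneState.zeros(())
        spikes, us = [], []
        for _ in range(6):
            state, s = lif_step(state, np.asarray(0.4), p)
            spikes.append(float(s))
            us.append(float(state.u))
        assert spikes == [0, 1, 0, 1, 0, 1]
        assert us == pytest.approx([0.4, 0.6, 0.4, 0.6, 0.4, 0.6])

    def test_hard_reset_leaves_only_input(self):
        p = NeuronParams(mode="lif", lif_decay=0.9)
        state = make_state(u=3.0, spike=1.0)
        state, _ = lif_step(state, np.asarray(0.2), p)
        assert state.u == pytest.approx(0.2)


class TestSurrogate:
    def test_window_centre(self):
        assert surrogate_grad(np.asarray(0.5), NeuronParams()) == pytest.approx(1.0)

    def test_outside_window(self):
        assert surrogate_grad(np.asarray(1.2), NeuronParams()) == pytest.approx(0.0)

    @pytest.mark.parametrize("a1", [0.5, 1.0, 2.0])
    def test_numeric_integral_is_one(self, a1):
        p = NeuronParams(a1=a1)
        u = np.linspace(-5, 5, 200001)
        integral = np.trapezoid(surrogate_grad(u, p), u)
        assert integral == pytest.approx(1.0, abs=2e-4)


class TestTypes:
    @pytest.mark.parametrize("kwargs", [
        {"v_th": 0.0}, {"a1": -1.0}, {"lif_decay": 0.0}, {"lif_decay": 1.5},
        {"dt": 0.0}, {"capacitance": -1.0}, {"mode": "izhikevich"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NeuronParams(**kwargs)

    def test_params_yaml_roundtrip(self):
        p = NeuronParams(v_th=0.7, g_na=0.2, mode="lif")
        assert NeuronParams.from_dict(p.to_dict()) == p

    def test_spike_train_must_be_binary(self):
        with pytest.raises(ValueError):
            SpikeTrain(values=np.full((8, 1, 2, 2), 0.5), t_steps=8)

    def test_spike_train_leading_dim(self):
        with pytest.raises(ValueError):
            SpikeTrain(values=np.zeros((4, 1, 2, 2)), t_steps=8)

    def test_spike_train_rate(self):
        v = np.zeros((8, 1)); v[:4] = 1
        assert SpikeTrain(values=v, t_steps=8).rate[0] == pytest.approx(0.5)
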