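"""Unit tests for the five learning rules and their traces."""

import numpy as np
import pytest

from heterochunk.plasticity import (
    PlasticityParams,
    TraceState,
    WeightSet,
    cubic_drift,
    freeze,
    thaw,
    update_competition,
    update_P,
    update_Q,
    update_Q_reduced,
    update_R,
    update_traces,
)


@pytest.fixture
def params():
    return PlasticityParams()


class TestProjectionRule:
    def test_gated_by_postsynaptic_activity(self, params):
        P = np.random.default_rng(0).random((5, 3))
        out = update_P(P, np.zeros(3), np.ones(5), 0.01, params.tau_P)
        assert np.array_equal(out, P)

    def test_column_converges_to_input(self, params):
        """With one active mode held on a constant normalized input, the
        mode's column relaxes to the input (fixed point of the rule)."""
        rng = np.random.default_rng(1)
        s = rng.random(6)
        s *= params.C / s.sum()
        P = rng.random((6, 2)) * 0.1
        x = np.array([1.0, 0.0])
        dt = 0.02
        for _ in range(int(20 * params.tau_P / dt)):
            P = update_P(P, x, s, dt, params.tau_P)
        assert np.allclose(P[:, 0], s, atol=1e-4)
        # column sum tends to C for normalized inputs
        assert abs(P[:, 0].sum() - params.C) < 1e-3

    def test_entries_remain_nonnegative(self, params):
        P = np.zeros((4, 2))
        out = update_P(P, np.ones(2), np.ones(4), 0.01, params.tau_P)
        assert np.all(out >= 0)


class TestTraces:
    def test_steady_state_is_tau_times_activity(self, params):
        tr = TraceState.zeros(2, 2)
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 2.0])
        for _ in range(int(30 * params.tau_A_y / 0.01)):
            tr = update_traces(tr, x, y, 0.01, params)
        assert tr.a_x[0] == pytest.approx(params.tau_A * 1.0, rel=1e-3)
        assert tr.a_y[1] == pytest.approx(params.tau_A_y * 2.0, rel=1e-3)

    def test_decay_to_zero_without_activity(self, params):
        tr = TraceState(np.ones(2), np.ones(2))
        for _ in range(int(20 * params.tau_A_y / 0.01)):
            tr = update_traces(tr, np.zeros(2), np.zeros(2), 0.01, params)
        assert np.all(tr.a_x < 1e-6) and np.all(tr.a_y < 1e-6)

    def test_transition_is_detectable(self, params):
        """A pulse in mode 0 followed by activity in mode 1 leaves a positive
        product x_1 * trace_0 (the learning-window signature)."""
        tr = TraceState.zeros(2, 1)
        dt = 0.02
        for _ in range(int(3.0 / dt)):  # mode 0 active
            tr = update_traces(tr, np.array([1.0, 0.0]), np.zeros(1), dt, params)
        x = np.array([0.0, 1.0])  # mode 1 takes over
        tr = update_traces(tr, x, np.zeros(1), dt, params)
        assert x[1] * tr.a_x[0] > 0.5 * params.tau_A


class TestBistableCubic:
    def test_zeros_are_the_prescribed_triple(self, params):
        lo, mid, hi = params.V_low, params.V_mid, params.V_high
        for w in (lo, mid, hi):
            assert cubic_drift(w, lo, mid, hi, 1.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("start,target", [
        (0.71, 1.15), (0.69, 0.3), (1.3, 1.15), (0.05, 0.3),
    ])
    def test_basin_convergence_scalar_ode(self, params, start, target):
        """Integrating the scalar weight ODE from either side of the unstable
        point converges to the corresponding stable state."""
        w = start
        for _ in range(400_000):
            w += 0.01 * cubic_drift(w, params.V_low, params.V_mid,
                                    params.V_high, 1.0)
        assert w == pytest.approx(target, abs=1e-6)

    def test_unstable_point_is_stationary(self, params):
        w = params.V_mid
        for _ in range(1000):
            w += 0.01 * cubic_drift(w, params.V_low, params.V_mid,
                                    params.V_high, 1.0)
        assert w == pytest.approx(params.V_mid)


class TestCompetitionRule:
    def test_diagonal_untouched(self, params):
        V = np.full((3, 3), 1.0)
        tr = TraceState(np.full(3, 10.0), np.zeros(1))
        out = update_competition(V, tr, np.full(3, 10.0), 0.01, params, "x")
        assert np.allclose(np.diag(out), 1.0)

    def test_transition_depresses_forward_potentiates_reverse(self, params):
        """At a transition a -> b (b active now, trace of a still high) the
        forward weight V[a, b] moves toward the low state and the reverse
        weight V[b, a] toward the high state."""
        V = np.full((2, 2), 1.0)
        x = np.array([0.1, 8.0])        # b = 1 active now
        tr = TraceState(np.array([12.0, 0.1]), np.zeros(1))  # a = 0 recent
        out = update_competition(V, tr, x, 0.01, params, "x")
        assert out[0, 1] < 1.0 < out[1, 0]

    def test_no_change_without_transitions(self, params):
        """A single steadily active mode leaves the off-diagonal weights at
        their bistable resting values (matched potentiation/depression)."""
        V = np.array([[1.0, params.V_high], [params.V_high, 1.0]])
        x = np.array([8.0, 0.0])
        tr = TraceState(np.array([params.tau_A * 8.0, 0.0]), np.zeros(1))
        out = V.copy()
        for _ in range(2000):
            out = update_competition(out, tr, x, 0.01, params, "x")
        assert np.allclose(out, V, atol=1e-9)


class TestQRule:
    def test_coactivity_potentiates_lone_cm_depotentiates(self, params):
        Q = np.full((2, 1), 0.2)
        x = np.array([8.0, 0.0])
        y = np.array([2.0])
        out = update_Q(Q, x, y, 0.01, params)
        assert out[0, 0] > 0.2      # co-active pair
        assert out[1, 0] < 0.2      # CM active alone for this EM

    def test_heterosynaptic_term_inactive_below_limit(self, params):
        """With efferent sums under m_H the competition term contributes
        exactly zero (rectifier)."""
        Q = np.full((2, 3), params.m_H / 6)  # row sums m_H / 2
        a = update_Q(Q, np.zeros(2), np.zeros(3), 0.01, params)
        p2 = PlasticityParams(eps_H=0.0)
        b = update_Q(Q, np.zeros(2), np.zeros(3), 0.01, p2)
        assert np.array_equal(a, b)

    def test_heterosynaptic_term_caps_efferent_sum(self, params):
        Q = np.full((1, 4), 2.0)  # row sum far above m_H
        p = PlasticityParams(alpha_Q=0.0, gamma_d_Q=params.gamma_d_Q)
        out = update_Q(Q, np.zeros(1), np.zeros(4), 0.01, p)
        assert np.all(out < 2.0)

    def test_small_signal_reduction_identity(self):
        """The full rule with linear gating, zero thresholds, no
        heterosynaptic term, zero lower bound and the rate degeneracy
        tau_Q = gamma_d equals the reduced one-line rule to machine
        precision on random states."""
        rng = np.random.default_rng(4)
        p = PlasticityParams(
            theta_p_Q=0.0, theta_d_Q=0.0, eps_H=0.0, Q_low=0.0,
            alpha_Q=1e-300,  # cubic off: the reduction drops it
            gamma_p_Q=6.0, gamma_d_Q=2.0, tau_Q=2.0,
        )
        for _ in range(20):
            Q = rng.random((5, 4)) * p.Q_high
            x = rng.random(5) * 3
            y = rng.random(4) * 2
            full = update_Q(Q, x, y, 0.01, p, gate="linear")
            red = update_Q_reduced(Q, x, y, 0.01, p)
            assert np.allclose(full, red, rtol=0, atol=1e-15)


class TestRRule:
    def test_coactivity_disinhibits(self, params):
        R = np.full((1, 2), 1.5)
        x = np.array([8.0, 0.0])
        y = np.array([2.0])
        out = update_R(R, x, y, 0.01, params)
        assert out[0, 0] < 1.5      # member: inhibits less
        assert out[0, 1] > 1.5      # non-member: inhibits more

    def test_silent_cm_leaves_only_the_cubic(self, params):
        R = np.full((1, 2), 0.4)    # below the unstable point
        out = R.copy()
        for _ in range(30_000):
            out = update_R(out, np.zeros(2), np.zeros(1), 0.05, params)
        assert np.allclose(out, params.R_low, atol=1e-3)


class TestFreezeThaw:
    def test_freeze_disables_and_thaw_restores(self, params):
        f = freeze(params)
        assert not any([f.learn_P, f.learn_V, f.learn_W, f.learn_Q, f.learn_R])
        t = thaw(f)
        assert all([t.learn_P, t.learn_V, t.learn_W, t.learn_Q, t.learn_R])

    def test_partial_freeze(self, params):
        f = freeze(params, ("Q", "R"))
        assert f.learn_P and f.learn_V and f.learn_W
        assert not f.learn_Q and not f.learn_R


class TestValidation:
    def test_inverted_triple_rejected(self):
        with pytest.raises(ValueError):
            PlasticityParams(V_low=1.0, V_mid=0.5, V_high=1.5)

    def test_weight_set_shape_checks(self):
        with pytest.raises(ValueError):
            WeightSet(np.zeros((4, 3)), np.zeros((3, 3)), np.zeros((2, 2)),
                      np.zeros((3, 3)), np.zeros((2, 3)))

    def test_weight_set_rejects_negative_entries(self):
        P = np.zeros((4, 3))
        V = np.zeros((3, 3))
        W = np.zeros((2, 2))
        Q = np.zeros((3, 2))
        R = np.full((2, 3), -0.1)
        with pytest.raises(ValueError):
            WeightSet(P, V, W, Q, R)
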