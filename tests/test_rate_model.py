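"""Homogeneous-population dynamics, plasticity coupling and closed forms."""

import numpy as np
import pytest

from ndfmem.plasticity import PlasticityConfig
from ndfmem.rate import (BalanceNotReachable, RateModelParams, RateState,
                         TrialProtocol, balanced_final_rate, convergence_check,
                         homeostatic_oscillation_frequency, normalize_params,
                         rate_derivative, run_session, run_trial,
                         simulate_trial_reduced, step_full, step_reduced,
                         trials_to_criterion, vector_field)


@pytest.mark.parametrize(
    "r, W_exc, W_inh, inp, expected",
    [
        (10.0, 500.0, 500.0, 0.0, -10.0 / 501.0),      # leak only, w_net = 0
        (123.4, 501.0, 500.0, 0.0, 0.0),               # w_net = 1 cancels the leak
        (0.0, 500.0, 500.0, 1000.0, 1000.0 / 501.0),   # pure input drive
    ],
)
def test_rate_derivative_closed_form(r, W_exc, W_inh, inp, expected):
    params = RateModelParams(W_inh=W_inh)
    state = RateState(r=r, W_exc=W_exc)
    assert rate_derivative(state, params, inp) == pytest.approx(expected, abs=1e-12)


def test_rate_derivative_rejects_nonfinite_input(rate_params):
    with pytest.raises(ValueError):
        rate_derivative(RateState(r=1.0, W_exc=500.0), rate_params, np.inf)


def test_step_reduced_first_order_euler(rate_params):
    state = RateState(r=20.0, W_exc=480.0)
    dt = 1e-4
    drdt = rate_derivative(state, rate_params, 100.0)
    out = step_reduced(state, rate_params, 100.0, dt)
    assert out.r == pytest.approx(state.r + dt * drdt, rel=1e-12)


def test_step_reduced_overflow_guard_names_dt():
    # strong runaway excitation with a large step trips the instability guard
    params = RateModelParams(W_inh=500.0)
    state = RateState(r=1.0, W_exc=5e5)
    with pytest.raises(RuntimeError, match="dt"):
        for _ in range(2000):
            state = step_reduced(state, params, 0.0, 5.0)


def test_perturbed_decay_time_constant(rate_params):
    """10% deficit decays exponentially with tau_eff = (tau+w_der)/(1+50)."""
    proto = TrialProtocol()
    t, r = simulate_trial_reduced(rate_params, 450.0, 500.0, proto, dt=0.02)
    delay = t >= proto.t_stim
    td = t[delay] - proto.t_stim
    rd = r[delay]
    tau_eff = 501.0 / 51.0
    sel = (td > 0) & (rd > 1e-6)
    expected = rd[sel][0] * np.exp(-(td[sel] - td[sel][0]) / tau_eff)
    assert rd[sel] == pytest.approx(expected, rel=2e-2)


def test_step_full_fixed_point_with_leak_compensated(rate_params):
    # s_exc = s_inh = r is stationary once W_exc - W_inh = tau cancels the leak
    state = RateState(r=30.0, W_exc=rate_params.W_inh + rate_params.tau,
                      s_exc=30.0, s_inh=30.0)
    out = step_full(state, rate_params, 0.0, 0.01)
    assert out.r == pytest.approx(30.0)
    assert out.s_exc == pytest.approx(30.0)
    assert out.s_inh == pytest.approx(30.0)


class TestRunTrial:
    def test_no_plasticity_leaves_weight_unchanged(self, rate_params, protocol, rng):
        cfg = PlasticityConfig(rule="differential", alpha_d=0.0)
        state = RateState(r=0.0, W_exc=450.0)
        out, rec = run_trial(state, rate_params, protocol, cfg, rng)
        assert out.W_exc == 450.0

    def test_leak_compensated_weight_holds_activity(self, rate_params, protocol, rng):
        """W_exc = W_inh + tau gives w_net = 1: drift < 1% over the delay."""
        state = RateState(r=0.0, W_exc=rate_params.W_inh + 1.0)
        _, rec = run_trial(state, rate_params, protocol, None, rng)
        assert abs(rec.r_end_delay - rec.r_end_stim) / rec.r_end_stim < 0.01

    def test_balanced_weight_decays_at_leak_rate(self, rate_params, protocol, rng):
        """W_exc = W_inh leaves only the leak: decay factor exp(-300/501)."""
        state = RateState(r=0.0, W_exc=rate_params.W_inh)
        _, rec = run_trial(state, rate_params, protocol, None, rng)
        factor = rec.r_end_delay / rec.r_end_stim
        assert factor == pytest.approx(np.exp(-300.0 / 501.0), rel=1e-2)

    def test_perturbed_activity_vanishes_within_trial(self, rate_params, protocol, rng):
        state = RateState(r=0.0, W_exc=450.0)
        _, rec = run_trial(state, rate_params, protocol, None, rng)
        assert rec.r_end_delay < 0.01 * rec.r_end_stim

    def test_activity_reset_between_trials(self, rate_params, protocol, rng):
        state = RateState(r=0.0, W_exc=500.0)
        out, _ = run_trial(state, rate_params, protocol, None, rng)
        assert out.r == 0.0


class TestRunSession:
    def test_differential_ratio_monotone_to_balance(self, protocol, rng):
        params = RateModelParams(W_inh=500.0, W_exc0=450.0)
        cfg = PlasticityConfig(rule="differential", alpha_d=0.01)
        trace = run_session(params, protocol, cfg, 200, rng)
        ratio = trace.ratio
        below = ratio < 0.99
        assert np.all(np.diff(ratio[below]) >= 0)
        assert ratio[-1] == pytest.approx(1.0, abs=0.01)

    def test_zero_perturbation_stays_balanced(self, protocol, rng):
        params = RateModelParams(W_inh=500.0, W_exc0=500.0)
        cfg = PlasticityConfig(rule="differential", alpha_d=0.01)
        trace = run_session(params, protocol, cfg, 50, rng)
        assert np.all(np.abs(trace.ratio - 1.0) < 0.003)

    def test_homeostatic_low_target_rate_leaves_deficit(self, protocol, rng):
        """r0 below the mean delay-start rate biases the balance downward."""
        params = RateModelParams(W_inh=500.0, W_exc0=450.0)
        cfg = PlasticityConfig(rule="homeostatic", alpha_h=4e-8, r0=25.0)
        trace = run_session(params, protocol, cfg, 1200, rng)
        assert trace.ratio[-200:].mean() < 1.0

    def test_homeostatic_variability_grows_with_rate(self, protocol):
        """Faster homeostatic learning oscillates more around balance."""
        params = RateModelParams(W_inh=500.0, W_exc0=450.0)
        stds = []
        for alpha in (4e-8, 2e-6):
            cfg = PlasticityConfig(rule="homeostatic", alpha_h=alpha, r0=50.0)
            trace = run_session(params, TrialProtocol(), cfg, 1200,
                                np.random.default_rng(8))
            stds.append(trace.ratio[-400:].std())
        assert stds[1] > 2 * stds[0]

    def test_saturating_always_on_recovers(self):
        """Short strong stimulus with the always-on saturating rule still
        converges to balance (saturation prevents stimulus-epoch unlearning)."""
        params = RateModelParams(W_inh=500.0, W_exc0=450.0, c=10000.0)
        proto = TrialProtocol(t_stim=10.0)
        cfg = PlasticityConfig(rule="saturating_differential", alpha_d=0.01,
                               K=1.0, always_on=True)
        trace = run_session(params, proto, cfg, 300, np.random.default_rng(4))
        assert trace.ratio[-30:].mean() == pytest.approx(1.0, abs=0.01)


def test_vector_field_on_balance_line(rate_params):
    r = np.array([0.0, 10.0, 50.0])
    W = np.full_like(r, rate_params.W_inh)
    drdt, dWdt = vector_field(r, W, rate_params, alpha=0.01)
    assert drdt == pytest.approx(-r / 501.0)
    assert dWdt == pytest.approx(0.01 * r**2 / 501.0)
    # below balance the weight grows for any positive rate
    drdt2, dWdt2 = vector_field(np.array([5.0]), np.array([400.0]), rate_params, 0.01)
    assert dWdt2[0] > 0


class TestTrialsToCriterion:
    def _trace(self, W):
        from ndfmem.rate import LearningTrace

        W = np.asarray(W, dtype=float)
        n = W.size
        z = np.zeros(n)
        return LearningTrace(np.arange(1, n + 1), z, z, z, W, 500.0)

    def test_already_at_criterion_counts_first_trial(self):
        assert trials_to_criterion(self._trace([495.0, 496.0])) == 1

    def test_monotone_crossing(self):
        assert trials_to_criterion(self._trace([480.0, 490.0, 496.0, 499.0])) == 3

    def test_never_reached_sentinel(self):
        assert trials_to_criterion(self._trace([450.0, 460.0])) == -1

    def test_faster_learning_reaches_criterion_sooner(self, protocol):
        counts = []
        for alpha in (0.01, 0.02):
            params = RateModelParams(W_inh=500.0, W_exc0=450.0)
            cfg = PlasticityConfig(rule="differential", alpha_d=alpha)
            trace = run_session(params, protocol, cfg, 200, np.random.default_rng(7))
            counts.append(trials_to_criterion(trace))
        assert counts[1] < counts[0]


class TestNormalization:
    def test_winh_cubed_equivalence(self):
        k = 2.0
        a = normalize_params(RateModelParams(W_inh=500.0), 0.01)
        b = normalize_params(RateModelParams(W_inh=k * 500.0), 0.01 * k**3)
        assert a.alpha_eff == pytest.approx(b.alpha_eff, rel=1e-12)

    def test_input_squared_equivalence(self):
        k = 0.5
        a = normalize_params(RateModelParams(W_inh=500.0, c=500.0 * k), 0.01)
        b = normalize_params(RateModelParams(W_inh=500.0, c=500.0), 0.01 * k**2)
        assert a.alpha_eff == pytest.approx(b.alpha_eff, rel=1e-12)

    def test_identity_scaling(self):
        a = normalize_params(RateModelParams(), 0.01)
        b = normalize_params(RateModelParams(), 0.01)
        assert a == b

    @pytest.mark.parametrize("k", [0.5, 2.0])
    def test_simulated_sessions_collapse_after_normalization(self, k, protocol):
        """Raw sessions at (alpha, W_inh) and (alpha*k^3, k*W_inh) overlay in
        normalized coordinates (up to the O(1/W_inh) leak correction)."""
        p1 = RateModelParams(W_inh=500.0, W_exc0=450.0)
        p2 = RateModelParams(W_inh=k * 500.0, W_exc0=k * 450.0)
        c1 = PlasticityConfig(rule="differential", alpha_d=0.01)
        c2 = PlasticityConfig(rule="differential", alpha_d=0.01 * k**3)
        t1 = run_session(p1, protocol, c1, 60, np.random.default_rng(3))
        t2 = run_session(p2, protocol, c2, 60, np.random.default_rng(3))
        # the raw systems differ from the normalized one by the O(1/W_inh)
        # leak correction, which bounds how closely the sessions can collapse
        tol = 10.0 / min(p1.W_inh, p2.W_inh)
        assert t1.ratio == pytest.approx(t2.ratio, abs=tol)


class TestBalancedFinalRate:
    def test_zero_perturbation_returns_initial(self):
        assert balanced_final_rate(50.0, 0.0, 0.01, 500.0, 500.0) == 50.0

    def test_alpha_p_ratio_invariance(self):
        a = balanced_final_rate(60.0, 0.02, 0.01, 500.0, 500.0)
        b = balanced_final_rate(60.0, 0.04, 0.02, 500.0, 500.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_unreachable_balance_signalled(self):
        with pytest.raises(BalanceNotReachable):
            balanced_final_rate(1.0, 0.5, 0.01, 500.0, 500.0)

    def test_matches_normalized_trajectory(self):
        """Integrating the normalized system from w = 1-p to balance lands on
        the closed-form final rate within 0.5%."""
        pred = balanced_final_rate(60.0, 0.02, 0.01, 500.0, 500.0)
        system = normalize_params(RateModelParams(W_inh=500.0), 0.01)
        _, rn, w = system.simulate(60.0, 0.98, 20000.0, n_eval=5000)
        assert w[-1] == pytest.approx(1.0, abs=1e-6)
        assert rn[-1] == pytest.approx(pred, rel=5e-3)


def test_oscillation_frequency_value_and_scaling():
    omega = homeostatic_oscillation_frequency(4e-8, 50.0)
    assert omega == pytest.approx(np.sqrt(2e-6), rel=1e-12)
    assert homeostatic_oscillation_frequency(16e-8, 50.0) == pytest.approx(2 * omega)


def test_euler_step_converged(rate_params, protocol):
    """Halving the default step changes a trial trajectory by < 0.5%."""
    assert convergence_check(rate_params, protocol, 500.0, 450.0, dt=0.1) < 0.005
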