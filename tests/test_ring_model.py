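"""Ring-network construction, stimulus model and trial dynamics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ndfmem.plasticity import PlasticityConfig
from ndfmem.ring import (ConnectivitySet, RingParams, RingState,
                         build_connectivity, compute_tuning, run_ring_trial,
                         run_learning_session, step_ring, stimulus_spatial,
                         stimulus_temporal, wrapped_distance)


class TestWrappedDistance:
    @pytest.mark.parametrize("a, b, expected", [
        (0.0, 0.0, 0.0),
        (np.pi / 2, -np.pi / 2, np.pi),          # antipodes are maximally distant
        (0.9 * np.pi, -0.9 * np.pi, 0.2 * np.pi),  # wrap across the branch cut
    ])
    def test_values(self, a, b, expected):
        assert wrapped_distance(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-np.pi, np.pi), st.floats(-np.pi, np.pi))
    def test_symmetric_and_bounded(self, a, b):
        d = wrapped_distance(a, b)
        assert d == pytest.approx(wrapped_distance(b, a))
        assert 0.0 <= d <= np.pi + 1e-12

    def test_literal_mod_pi_convention_exposed(self):
        # the mod-pi reading couples antipodes maximally; kept selectable
        assert wrapped_distance(np.pi / 2, -np.pi / 2, "mod_pi") == pytest.approx(0.0)


class TestBuildConnectivity:
    def test_diagonal_equals_amplitude(self):
        W = build_connectivity(100.0, 0.2 * np.pi, 64)
        assert W.diagonal() == pytest.approx(100.0)

    def test_one_width_off_diagonal(self):
        # pick N so one grid step equals sigma exactly
        sigma = 2 * np.pi / 16
        W = build_connectivity(100.0, sigma, 16)
        assert W[1, 0] == pytest.approx(100.0 * np.exp(-1.0), rel=1e-12)

    def test_rows_are_circular_shifts(self):
        W = build_connectivity(7.0, 0.3, 32)
        for i in range(32):
            assert np.array_equal(W[i], np.roll(W[0], i))

    def test_eigenvalues_match_dft_of_first_row(self):
        W = build_connectivity(100.0, 0.2 * np.pi, 32)
        eig = np.sort(np.linalg.eigvals(W).real)
        dft = np.sort(np.fft.fft(W[0]).real)
        assert eig == pytest.approx(dft, abs=1e-9)


class TestStimulus:
    def test_spatial_peak_and_floor(self, ring_params):
        vec = stimulus_spatial(0.0, ring_params)
        i0 = np.argmin(np.abs(ring_params.theta_grid))
        assert vec[i0] == pytest.approx(270.0 + 200.0)
        assert vec.min() > 200.0  # baseline floor everywhere

    def test_spatial_value_at_one_width(self, ring_params):
        # evaluate on a grid point at exactly sigma_o from the center
        theta0 = ring_params.theta_grid[0]
        target = theta0 + ring_params.sigma_o  # 0.25*pi = 8 grid steps at N=64
        idx = np.argmin(np.abs(ring_params.theta_grid - target))
        vec = stimulus_spatial(theta0, ring_params)
        assert vec[idx] == pytest.approx(270.0 * np.exp(-1.0) + 200.0, rel=1e-9)

    def test_spatial_shift_equivariance(self, ring_params):
        v0 = stimulus_spatial(ring_params.theta_grid[0], ring_params)
        v3 = stimulus_spatial(ring_params.theta_grid[3], ring_params)
        assert np.allclose(np.roll(v0, 3), v3)

    @pytest.mark.parametrize("t, expected", [
        (0.0, 0.0),
        (100.0, 1.0 - np.exp(-1.0)),                       # t = tau_o < t_stim
        (600.0, (1.0 - np.exp(-5.0)) * np.exp(-1.0)),      # t_stim + tau_o
    ])
    def test_temporal_values(self, ring_params, t, expected):
        assert stimulus_temporal(t, ring_params) == pytest.approx(expected, rel=1e-12)

    def test_temporal_continuity_at_stimulus_offset(self, ring_params):
        eps = 1e-9
        a = stimulus_temporal(ring_params.t_stim - eps, ring_params)
        b = stimulus_temporal(ring_params.t_stim + eps, ring_params)
        assert a == pytest.approx(b, abs=1e-6)

    def test_temporal_range_checked(self, ring_params):
        with pytest.raises(ValueError):
            stimulus_temporal(-1.0, ring_params)
        with pytest.raises(ValueError):
            stimulus_temporal(ring_params.t_total, ring_params)


class TestStepRing:
    def test_zero_state_zero_input_stays_zero(self, ring_params, table1_conn):
        state = RingState.zeros(ring_params.N)
        out = step_ring(state, table1_conn, np.zeros(ring_params.N), 0.0, ring_params)
        for name in ("r_E", "r_I", "s_EE", "s_EI", "s_IE", "s_II"):
            assert np.all(getattr(out, name) == 0.0)

    def test_pure_excitation_grows_toward_input(self, ring_params):
        conn = ConnectivitySet.from_params(ring_params)
        conn.W_EI = np.zeros_like(conn.W_EI)  # silence inhibition onto E
        state = RingState.zeros(ring_params.N)
        stim = np.full(ring_params.N, 50.0)
        out = step_ring(state, conn, stim, 1.0, ring_params)
        assert np.all(out.r_E > 0.0)

    def test_large_dt_rejected(self, ring_params, table1_conn):
        with pytest.raises(ValueError):
            step_ring(RingState.zeros(ring_params.N), table1_conn,
                      np.zeros(ring_params.N), 0.0, ring_params, dt=5.0)


class TestRingTrial:
    def test_unperturbed_bump_peaks_at_stimulus(self, small_ring_params):
        conn = ConnectivitySet.from_params(small_ring_params)
        rec = run_ring_trial(conn, 0.0, small_ring_params)
        r = rec.r_E_end_delay
        i0 = np.argmin(np.abs(small_ring_params.theta_grid))
        assert r.argmax() == i0
        # bump-shaped: pronounced peak at the stimulus, clearly lower far tail
        # (the tail carries shallow ripples from the residual mode mixture)
        d = wrapped_distance(small_ring_params.theta_grid, 0.0)
        near, far = r[d < 0.2 * np.pi], r[d > 0.5 * np.pi]
        assert near.min() > 1.5 * far.max()
        assert r.max() > 2.0 * far.max()

    def test_rates_stay_nonnegative(self, short_ring_params):
        conn = ConnectivitySet.from_params(short_ring_params)
        rec = run_ring_trial(conn, 0.0, short_ring_params)
        assert rec.r_E_end_delay.min() >= -1e-9
        assert rec.r_I_end_delay.min() >= -1e-9

    def test_no_plasticity_preserves_connectivity_bitwise(self, short_ring_params):
        conn = ConnectivitySet.from_params(short_ring_params)
        before = conn.W_EE.copy()
        run_ring_trial(conn, 0.0, short_ring_params,
                       cfg=PlasticityConfig(rule="none"))
        assert np.array_equal(conn.W_EE, before)

    def test_global_perturbation_flattens_end_of_delay(self, small_ring_params):
        from ndfmem.perturbation import PerturbationSpec, apply_perturbation

        conn = ConnectivitySet.from_params(small_ring_params)
        rec0 = run_ring_trial(conn, 0.0, small_ring_params)
        connp = ConnectivitySet.from_params(small_ring_params)
        connp.W_EE = apply_perturbation(connp.W_EE, PerturbationSpec("global", 0.1))
        recp = run_ring_trial(connp, 0.0, small_ring_params)
        # activity collapses toward baseline; spatial modulation nearly gone
        assert recp.r_E_end_delay.max() < 0.05 * rec0.r_E_end_delay.max()
        assert np.ptp(recp.r_E_end_delay) < 0.05 * np.ptp(rec0.r_E_end_delay)


def test_learning_session_draws_grid_locations_and_evaluates(small_ring_params):
    conn = ConnectivitySet.from_params(small_ring_params)
    cfg = PlasticityConfig(rule="none")
    trace = run_learning_session(conn, small_ring_params, cfg, 3, None,
                                 np.random.default_rng(0), n_repeats=2)
    assert set(np.round(trace.theta0, 12)) <= set(np.round(small_ring_params.theta_grid, 12))
    # evaluations at session start and end
    assert list(trace.eval_trial) == [0, 3]
    assert trace.decoding_error.shape == (2,)


def test_tuning_matrix_is_circulant_for_unperturbed_ring(short_ring_params):
    tuning = compute_tuning(ConnectivitySet.from_params(short_ring_params),
                            short_ring_params)
    # stimulating one grid step over rotates the response by one neuron
    assert np.allclose(tuning.rates[:, 1], np.roll(tuning.rates[:, 0], 1),
                       atol=1e-9)
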