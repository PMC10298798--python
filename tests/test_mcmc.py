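"""Tests for the Metropolis–Hastings sampler and its proposals."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuroensemble.mcmc import (MCMCConfig, apply_omega_transition,
                                apply_weight_transition, bim_weight_proposal,
                                concentration_omega_probability,
                                concentration_t_probabilities,
                                effective_ensemble_count, initialize_state,
                                propose_concentration_omega,
                                propose_concentration_t, run_inference, sweep,
                                weight_hastings_ratio)
from neuroensemble.model import PriorHyperparameters

from conftest import random_state


class TestInitialization:
    def test_soft_state_is_valid(self):
        rng = np.random.default_rng(0)
        s = rng.random((6, 9))
        state = initialize_state(s, MCMCConfig(n_ensembles=4), rng)
        np.testing.assert_allclose(state.t.sum(axis=0), 1.0, atol=1e-12)
        assert state.omega.min() >= 0 and state.omega.max() <= 1
        np.testing.assert_array_equal(state.last_concentration,
                                      state.t.argmax(axis=0))

    def test_bim_state_is_onehot_binary(self):
        rng = np.random.default_rng(0)
        s = rng.integers(2, size=(6, 9)).astype(float)
        cfg = MCMCConfig(n_ensembles=4, mode="bim", alpha_new=1.0)
        state = initialize_state(s, cfg, rng)
        assert np.all(np.isin(state.t, [0.0, 1.0]))
        np.testing.assert_array_equal(state.t.sum(axis=0), 1.0)
        assert np.all(np.isin(state.omega, [0.0, 1.0]))

    def test_fixed_seed_is_bit_identical(self):
        s = np.random.default_rng(1).random((5, 7))
        cfg = MCMCConfig(n_ensembles=3)
        a = initialize_state(s, cfg, np.random.default_rng(9))
        b = initialize_state(s, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.omega, b.omega)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="alpha_new"):
            MCMCConfig(mode="soft", alpha_new=0.5)
        with pytest.raises(ValueError, match="mode"):
            MCMCConfig(mode="fuzzy")


class TestConcentrationProposals:
    def test_t_probabilities_two_occupied_ensembles(self):
        t = np.array([[0.2, 1.0, 0.0], [0.8, 0.0, 1.0]])
        p = concentration_t_probabilities(t, 0)
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_t_degenerate_mass(self):
        t = np.zeros((3, 4))
        t[1] = 1.0
        p = concentration_t_probabilities(t, 0)
        np.testing.assert_allclose(p, [0, 1, 0])

    def test_t_single_neuron_raises(self):
        with pytest.raises(ValueError, match="N >= 2"):
            propose_concentration_t(np.ones((2, 1)) / 2, 0,
                                    np.random.default_rng(0))

    def test_t_empirical_frequencies(self):
        rng = np.random.default_rng(3)
        t = rng.dirichlet(np.ones(3), size=5).T
        p = concentration_t_probabilities(t, 2)
        n = 100_000
        draws = np.array([propose_concentration_t(t, 2, rng)
                          for _ in range(n)])
        freq = np.bincount(draws, minlength=3) / n
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freq - p) < 3 * se + 1e-12)

    def test_omega_probability_and_complement(self):
        omega = np.array([[0.3], [1.0], [0.0]])
        assert concentration_omega_probability(omega, 0, 0) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        omega2 = np.ones((4, 1))
        assert all(propose_concentration_omega(omega2, 0, 0, rng) == 1
                   for _ in range(10))

    def test_omega_single_step_raises(self):
        with pytest.raises(ValueError, match="M >= 2"):
            concentration_omega_probability(np.ones((1, 1)), 0, 0)


class TestTransitions:
    def test_weight_transition_example(self):
        out = apply_weight_transition(np.array([0.5, 0.5]), 1, 0.5)
        np.testing.assert_allclose(out, [1 / 3, 2 / 3])

    @given(st.integers(0, 10_000), st.floats(0, 10))
    def test_weight_transition_stays_on_simplex(self, seed, alpha_t):
        rng = np.random.default_rng(seed)
        a = int(rng.integers(2, 6))
        t_i = rng.dirichlet(np.ones(a))
        out = apply_weight_transition(t_i, int(rng.integers(a)), alpha_t)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out.min() >= 0

    def test_weight_transition_identity_at_zero(self):
        t_i = np.array([0.25, 0.75])
        np.testing.assert_allclose(apply_weight_transition(t_i, 0, 0.0), t_i)

    @pytest.mark.parametrize("g, expected", [
        (1, 1000.5 / 1001), (0, 0.5 / 1001)])
    def test_omega_transition_large_alpha(self, g, expected):
        assert apply_omega_transition(0.5, g, 1000.0) == pytest.approx(expected)

    def test_omega_transition_identity_at_zero(self):
        assert apply_omega_transition(0.42, 1, 0.0) == pytest.approx(0.42)


class TestHastingsRatios:
    def test_same_labels_ratio_one(self):
        t = np.random.default_rng(0).dirichlet(np.ones(3), size=4).T
        assert weight_hastings_ratio(t, 0, 2, 2) == pytest.approx(1.0)

    def test_size_ratio_and_symmetry(self):
        t = np.zeros((2, 3))
        t[0, 1] = 1.0
        t[0, 2] = 0.5
        t[1, 2] = 0.5
        # excluding neuron 0: ensemble 0 holds 1.5, ensemble 1 holds 0.5
        assert weight_hastings_ratio(t, 0, 1, 0) == pytest.approx(3.0)
        assert weight_hastings_ratio(t, 0, 0, 1) == pytest.approx(1 / 3)

    def test_empty_target_rejects(self):
        t = np.zeros((2, 3))
        t[0] = 1.0
        assert weight_hastings_ratio(t, 0, 1, 0) == 0.0


class TestBimProposal:
    def test_alpha_new_zero_never_new(self):
        t = np.zeros((2, 3))
        t[0] = 1.0
        rng = np.random.default_rng(0)
        draws = {bim_weight_proposal(t, 0, 0.0, rng) for _ in range(50)}
        assert draws <= {0, 1}

    def test_new_ensemble_probability(self):
        t = np.zeros((2, 3))
        t[0, 1] = 1.0
        t[1, 2] = 1.0
        rng = np.random.default_rng(1)
        n = 40_000
        draws = np.array([bim_weight_proposal(t, 0, 2.0, rng)
                          for _ in range(n)])
        freq_new = (draws == 2).mean()
        assert freq_new == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))


class TestSweep:
    def test_zero_transition_parameters_leave_state_unchanged(self):
        rng = np.random.default_rng(5)
        s = rng.random((6, 8))
        cfg = MCMCConfig(n_ensembles=3, alpha_t=0.0, alpha_omega=0.0)
        state = initialize_state(s, cfg, rng)
        t0, w0 = state.t.copy(), state.omega.copy()
        for _ in range(5):
            sweep(state, s, cfg, rng)
        np.testing.assert_array_equal(state.t, t0)
        np.testing.assert_array_equal(state.omega, w0)

    def test_invariants_hold_after_many_sweeps(self):
        rng = np.random.default_rng(6)
        s = rng.random((8, 12))
        cfg = MCMCConfig(n_ensembles=4, alpha_t=0.5)
        state = initialize_state(s, cfg, rng)
        for _ in range(100):
            sweep(state, s, cfg, rng)
        np.testing.assert_allclose(state.t.sum(axis=0), 1.0, atol=1e-10)
        assert state.t.min() >= 0
        assert state.omega.min() >= 0 and state.omega.max() <= 1
        assert np.all((0 <= state.last_concentration)
                      & (state.last_concentration < 4))

    def test_bim_sweep_keeps_hard_state(self):
        rng = np.random.default_rng(7)
        s = rng.integers(2, size=(8, 12)).astype(float)
        cfg = MCMCConfig(n_ensembles=5, mode="bim", alpha_new=0.5)
        state = initialize_state(s, cfg, rng)
        for _ in range(50):
            sweep(state, s, cfg, rng)
        assert np.all(np.isin(state.t, [0.0, 1.0]))
        np.testing.assert_array_equal(state.t.sum(axis=0), 1.0)
        assert np.all(np.isin(state.omega, [0.0, 1.0]))

    def test_fixed_seed_trajectory_is_identical(self):
        s = np.random.default_rng(1).random((5, 7))
        cfg = MCMCConfig(n_ensembles=3, n_trials=2, n_sweeps=10, seed=11)
        r1 = run_inference(s, cfg)
        r2 = run_inference(s, cfg)
        for a, b in zip(r1.memberships, r2.memberships):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(r1.log_prob_traces, r2.log_prob_traces):
            np.testing.assert_array_equal(a, b)


class TestRunInference:
    def test_bookkeeping_single_trial(self):
        s = np.random.default_rng(2).random((4, 6))
        res = run_inference(s, MCMCConfig(n_ensembles=2, n_trials=1,
                                          n_sweeps=1))
        assert res.n_trials == 1
        assert len(res.log_prob_traces[0]) == 1
        assert res.seeds == [0]

    def test_trace_length_and_trial_seeds(self):
        s = np.random.default_rng(2).random((4, 6))
        cfg = MCMCConfig(n_ensembles=2, n_trials=3, n_sweeps=5, seed=100)
        res = run_inference(s, cfg)
        assert res.seeds == [100, 101, 102]
        assert all(len(tr) == 5 for tr in res.log_prob_traces)


class TestEffectiveEnsembleCount:
    def test_counting_cases(self):
        t = np.zeros((5, 6))
        t[0, :3] = 1.0
        t[1, 3:5] = 1.0
        t[2, 5] = 1.0
        assert effective_ensemble_count(t, eps=0.5) == 3
        uniform = np.full((4, 8), 0.25)
        assert effective_ensemble_count(uniform, eps=0.0) == 4
        uniform16 = np.full((16, 8), 1 / 16)
        assert effective_ensemble_count(uniform16, eps=1.0) == 0


class TestIncrementalRatios:
    def test_incremental_matches_full_recompute(self):
        """Single-site acceptance ratios equal full joint differences."""
        from neuroensemble.mcmc import (omega_log_posterior_ratio,
                                        weight_log_posterior_ratio)
        from neuroensemble.model import (compute_sufficient_stats,
                                         log_marginal_joint)
        rng = np.random.default_rng(12)
        for _ in range(40):
            n, m, a = rng.integers(2, 6), rng.integers(2, 6), rng.integers(1, 4)
            t, omega, s = random_state(rng, n, m, a)
            prior = PriorHyperparameters(*(rng.random(a) + 0.5
                                           for _ in range(7)))

            def full(tt, ww):
                return log_marginal_joint(
                    compute_sufficient_stats(tt, ww, s), prior)

            k, mu = rng.integers(m), rng.integers(a)
            new = rng.random()
            inc = omega_log_posterior_ratio(s, t, omega, prior, k, mu, new)
            w2 = omega.copy()
            w2[k, mu] = new
            assert inc == pytest.approx(full(t, w2) - full(t, omega),
                                        abs=1e-9)

            i = rng.integers(n)
            ti = rng.dirichlet(np.ones(a))
            inc = weight_log_posterior_ratio(s, t, omega, prior, i, ti)
            t2 = t.copy()
            t2[:, i] = ti
            assert inc == pytest.approx(full(t2, omega) - full(t, omega),
                                        abs=1e-9)
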