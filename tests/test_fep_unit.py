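import numpy as np
import pytest

from fep_rsi.fep_unit import (
    Environment,
    FepUnit,
    efe_components,
    expected_free_energy,
    expected_obs,
    expected_states,
    infer_state,
    run_unit,
    select_policy,
    unit_step,
    variational_free_energy,
)
from fep_rsi.generative_model import make_default_model

from oracles import bayes_posterior, efe_enumeration, negative_elbo, random_model


class TestInferState:
    def test_noise_free_identity_pins_the_observed_state(self):
        m = make_default_model(3, 0.0)
        q = infer_state(m, 1, np.full(3, 1 / 3))
        np.testing.assert_allclose(q, [0, 1, 0], atol=1e-12)

    def test_uninformative_likelihood_returns_the_prior(self):
        m = make_default_model(3, 0.0)
        m.A = np.full((3, 3), 1 / 3)
        prior = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(infer_state(m, 0, prior), prior, atol=1e-12)

    def test_matches_bayes_rule_enumeration(self):
        m = make_default_model(3, 0.2)
        prior = np.full(3, 1 / 3)
        np.testing.assert_allclose(
            infer_state(m, 0, prior),
            bayes_posterior(m.A, 0, prior),
            atol=1e-12,
        )

    def test_observation_out_of_range(self, default_model):
        with pytest.raises(IndexError):
            infer_state(default_model, 7, np.full(5, 0.2))

    def test_random_battery_matches_bayes_oracle(self, rng):
        """Exact-inference equivalence over random models with random priors."""
        for _ in range(100):
            n = int(rng.integers(2, 7))
            m = random_model(rng, n)
            prior = rng.dirichlet(np.ones(n))
            o = int(rng.integers(n))
            np.testing.assert_allclose(
                infer_state(m, o, prior),
                bayes_posterior(m.A, o, prior),
                atol=1e-10,
            )


class TestVariationalFreeEnergy:
    def test_exact_posterior_under_uniform_prior_leaves_only_surprise(self):
        m = make_default_model(3, 0.2)
        prior = np.full(3, 1 / 3)
        q = m.A[0, :] / m.A[0, :].sum()
        F = variational_free_energy(m, q, 0, prior)
        assert F == pytest.approx(-np.log(m.A[0, :] @ prior), abs=1e-12)

    def test_any_other_belief_pays_a_positive_kl(self):
        m = make_default_model(3, 0.2)
        prior = np.full(3, 1 / 3)
        floor = -np.log(m.A[0, :] @ prior)
        q = np.array([0.5, 0.25, 0.25])
        assert variational_free_energy(m, q, 0, prior) > floor

    def test_equals_negative_elbo_by_enumeration(self):
        m = make_default_model(3, 0.2)
        prior = np.full(3, 1 / 3)
        q = np.array([0.5, 0.25, 0.25])
        assert variational_free_energy(m, q, 0, prior) == pytest.approx(
            negative_elbo(m.A, 0, prior, q), abs=1e-12
        )

    def test_negative_elbo_identity_on_random_battery(self, rng):
        """F and -ELBO coincide under uniform priors on random models."""
        for _ in range(100):
            n = int(rng.integers(2, 7))
            m = random_model(rng, n)
            prior = np.full(n, 1 / n)
            o = int(rng.integers(n))
            q = rng.dirichlet(np.ones(n))
            assert variational_free_energy(m, q, o, prior) == pytest.approx(
                negative_elbo(m.A, o, prior, q), abs=1e-10
            )


class TestExpectedStatesAndObs:
    def test_deterministic_move_up(self, default_model):
        q = np.eye(5)[1]
        np.testing.assert_allclose(
            expected_states(default_model, q, 0), np.eye(5)[2]
        )

    def test_move_down_clamps_at_zero(self, default_model):
        q = np.eye(5)[0]
        np.testing.assert_allclose(
            expected_states(default_model, q, 1), np.eye(5)[0]
        )

    def test_stay_is_identity(self, default_model):
        q = np.array([0.5, 0.5, 0, 0, 0])
        np.testing.assert_allclose(expected_states(default_model, q, 2), q)

    def test_expected_obs_reads_off_likelihood_column(self):
        m = make_default_model(3, 0.2)
        np.testing.assert_allclose(
            expected_obs(m, np.eye(3)[2]), [0.1, 0.1, 0.8]
        )


class TestExpectedFreeEnergy:
    def test_zero_when_likelihood_is_sharp_and_prediction_matches_preference(self):
        m = make_default_model(5, 0.0)
        m.C = expected_obs(m, expected_states(m, np.eye(5)[1], 2))
        assert expected_free_energy(m, np.eye(5)[1], 2) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_identity_likelihood_leaves_only_risk(self):
        m = make_default_model(5, 0.0)  # uniform C, zero column entropies
        for pi in range(3):
            amb, risk = efe_components(m, np.eye(5)[1], pi)
            assert amb == pytest.approx(0.0, abs=1e-10)
            assert risk >= 0

    def test_matches_term_by_term_enumeration_and_prefers_moving_up(
        self, default_model
    ):
        q = infer_state(default_model, 1, np.full(5, 0.2))
        G = []
        for pi in range(3):
            amb, risk = efe_enumeration(default_model, q, pi)
            assert amb >= 0 and risk >= 0
            assert expected_free_energy(default_model, q, pi) == pytest.approx(
                amb + risk, abs=1e-12
            )
            G.append(amb + risk)
        assert int(np.argmin(G)) == 0  # moving toward the preferred state

    def test_decomposition_on_random_battery(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            m = random_model(rng, n)
            q = rng.dirichlet(np.ones(n))
            pi = int(rng.integers(3))
            amb, risk = efe_components(m, q, pi)
            assert amb >= 0 and risk >= -1e-15
            assert expected_free_energy(m, q, pi) == pytest.approx(
                amb + risk, abs=1e-12
            )


class TestSelectPolicy:
    @pytest.mark.parametrize(
        "G, expected",
        [
            ((0.5, 1.2, 0.9), 0),
            ((1.0, 1.0, 2.0), 0),  # exact tie -> lowest index
            ((3.0, 2.9999, 3.0001), 1),
        ],
    )
    def test_argmin_with_tie_break(self, G, expected):
        assert select_policy(np.array(G)) == expected

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            select_policy(np.array([1.0, np.nan, 2.0]))

    def test_softmax_mode_is_seeded_and_favors_low_G(self):
        rng = np.random.default_rng(0)
        picks = [
            select_policy(np.array([0.1, 5.0, 5.0]), rng, temperature=1.0)
            for _ in range(50)
        ]
        assert picks.count(0) > 40
        rng2 = np.random.default_rng(0)
        picks2 = [
            select_policy(np.array([0.1, 5.0, 5.0]), rng2, temperature=1.0)
            for _ in range(50)
        ]
        assert picks == picks2


class TestUnitStep:
    def test_noise_free_perturbation_step(self, noise_free_model):
        """From state 1 with a sharp preference for 4: observe 1, believe 1,
        move up, the niche advances to 2."""
        unit = FepUnit(model=noise_free_model)
        env = Environment(true_state=1, n_states=5)
        rec = unit_step(unit, env, deterministic=True)
        assert rec.observation == 1
        assert rec.map_state == 1
        assert rec.posterior[1] == pytest.approx(1.0, abs=1e-12)
        assert rec.action == 0
        assert env.true_state == 2

    def test_zero_adjustment_equals_no_adjustment(self, default_model):
        results = []
        for adj in (None, np.zeros(5)):
            unit = FepUnit(model=default_model.copy())
            env = Environment(true_state=1, n_states=5)
            rng = np.random.default_rng(7)
            results.append(unit_step(unit, env, adj, rng))
        a, b = results
        assert a.observation == b.observation and a.action == b.action
        np.testing.assert_array_equal(a.posterior, b.posterior)
        assert a.F == b.F

    def test_noise_free_run_climbs_to_the_preferred_state_and_stays(
        self, noise_free_model
    ):
        recs = run_unit(noise_free_model, 1, 15, deterministic=True)
        states = [r.true_state for r in recs]
        assert states[:4] == [1, 2, 3, 4]
        assert all(s == 4 for s in states[3:])

    def test_prior_is_posterior_propagated_through_chosen_transition(
        self, default_model
    ):
        unit = FepUnit(model=default_model.copy())
        env = Environment(true_state=2, n_states=5)
        rec = unit_step(unit, env, None, np.random.default_rng(3))
        np.testing.assert_allclose(
            unit.prior,
            default_model.B[:, :, rec.action] @ rec.posterior,
            atol=1e-15,
        )
        assert unit.prior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_seeds_give_bitwise_identical_records(self, default_model):
        runs = [
            run_unit(default_model, 1, 15, rng=np.random.default_rng(42))
            for _ in range(2)
        ]
        for a, b in zip(*runs):
            assert a.true_state == b.true_state
            assert a.observation == b.observation
            assert a.action == b.action
            assert a.F == b.F
            np.testing.assert_array_equal(a.posterior, b.posterior)
            np.testing.assert_array_equal(a.G, b.G)
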