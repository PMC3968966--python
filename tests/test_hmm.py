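"""Unit and property tests for the covariate HMM core."""

import numpy as np
import pytest
from scipy.special import softmax

import trajclust as tc
from trajclust.hmm import (
    EMConfig,
    OverfitError,
    fit_em,
    forward_backward_posteriors,
    forward_log_likelihood,
    n_free_parameters,
    sample_trajectory,
    transition_matrix_at,
    uniform_parameters,
)
from trajclust.schema import DatasetSchema, Trajectory, TrajectoryError

from helpers import (
    brute_force_log_likelihood,
    brute_force_posteriors,
    enumerate_observation_space,
    model_from_tables,
    random_model,
)


# ---------------------------------------------------------------- transition


class TestTransitionMatrix:
    def test_zero_weights_give_uniform_rows(self, two_channel_schema):
        p = uniform_parameters(two_channel_schema, 2)
        x = two_channel_schema.encode_covariate_row([0])
        assert np.allclose(transition_matrix_at(p, x), 0.5)

    def test_intercept_logits_softmax(self, two_channel_schema):
        p = uniform_parameters(two_channel_schema, 2)
        # row logits (log 3, 0) -> (0.75, 0.25); reference is destination 0
        p.transition_weights[0, 1, 0] = -np.log(3.0)
        x = two_channel_schema.encode_covariate_row([1])
        row = transition_matrix_at(p, x)[0]
        assert np.allclose(row, [0.75, 0.25])

    def test_rows_sum_to_one_and_positive(self, two_channel_schema):
        rng = np.random.default_rng(0)
        p = random_model(two_channel_schema, 3, rng)
        x = two_channel_schema.encode_covariate_row([1])
        A = transition_matrix_at(p, x)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)
        assert (A > 0).all()

    def test_dimension_mismatch_raises(self, two_channel_schema):
        p = uniform_parameters(two_channel_schema, 2)
        with pytest.raises(ValueError, match="covariate_row"):
            transition_matrix_at(p, np.ones(5))

    def test_constant_in_time_without_covariate_weights(self, two_channel_schema):
        rng = np.random.default_rng(1)
        p = random_model(two_channel_schema, 2, rng)
        p.transition_weights[:, :, 1:] = 0.0
        x0 = two_channel_schema.encode_covariate_row([0])
        x1 = two_channel_schema.encode_covariate_row([1])
        assert np.allclose(
            transition_matrix_at(p, x0), transition_matrix_at(p, x1)
        )


# ------------------------------------------------------------------ emission


class TestEmissionLogProb:
    def test_independent_channels_multiply(self, two_channel_schema):
        p = uniform_parameters(two_channel_schema, 1)
        x = two_channel_schema.encode_covariate_row([0])
        # both channels uniform: 1/2 * 1/3
        lp = tc.emission_log_prob_at(p, 0, x, np.array([0, 2]))
        assert np.isclose(lp, np.log(0.5 / 3))

    def test_specified_probabilities(self, binary_schema):
        sch = DatasetSchema(
            observation_channels=(("u", ("x", "y")), ("v", ("x", "y")))
        )
        m = model_from_tables(
            sch,
            initial=[1.0],
            transition=[[1.0]],
            emissions=[np.array([[0.7, 0.3]]), np.array([[0.2, 0.8]])],
        )
        x = sch.encode_covariate_row([]) if sch.n_covariate_channels else np.ones(1)
        lp = tc.emission_log_prob_at(m, 0, x, np.array([0, 1]))
        assert np.isclose(lp, np.log(0.7 * 0.8))

    def test_out_of_range_category_raises(self, two_channel_schema):
        p = uniform_parameters(two_channel_schema, 1)
        x = two_channel_schema.encode_covariate_row([0])
        with pytest.raises(TrajectoryError):
            tc.emission_log_prob_at(p, 0, x, np.array([0, 3]))


# ------------------------------------------------------------------- forward


class TestForwardLikelihood:
    def test_deterministic_emissions_single_surviving_path(self, binary_schema):
        # pi = (1, 0); uniform transitions; state 0 emits A, state 1 emits B
        eps = 1e-12
        m = model_from_tables(
            binary_schema,
            initial=[1 - eps, eps],
            transition=[[0.5, 0.5], [0.5, 0.5]],
            emissions=[np.array([[1 - eps, eps], [eps, 1 - eps]])],
        )
        traj = Trajectory("s", np.array([[0], [0]]))
        assert np.isclose(forward_log_likelihood(m, traj), np.log(0.5), atol=1e-9)

    def test_uniform_model_gives_independent_coin_flips(self, binary_schema):
        p = uniform_parameters(binary_schema, 2)
        for L in (1, 3, 6):
            traj = Trajectory("s", np.zeros((L, 1), dtype=int))
            assert np.isclose(forward_log_likelihood(p, traj), L * np.log(0.5))

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_path_enumeration(self, trial, two_channel_schema):
        rng = np.random.default_rng(1000 + trial)
        S = int(rng.integers(1, 4))
        L = int(rng.integers(1, 7))
        p = random_model(
            two_channel_schema, S, rng, covariates_in_emissions=bool(trial % 2)
        )
        traj = Trajectory(
            "s",
            rng.integers(0, [2, 3], size=(L, 2)),
            rng.integers(0, 2, size=(L, 1)),
        )
        assert np.isclose(
            forward_log_likelihood(p, traj),
            brute_force_log_likelihood(p, traj),
            atol=1e-10,
        )

    def test_total_probability_sums_to_one(self, binary_schema):
        rng = np.random.default_rng(5)
        p = random_model(binary_schema, 2, rng)
        for L in (1, 2, 4):
            total = sum(
                np.exp(forward_log_likelihood(p, Trajectory("s", obs)))
                for obs in enumerate_observation_space(binary_schema, L)
            )
            assert np.isclose(total, 1.0, atol=1e-10)


# ---------------------------------------------------------------- posteriors


class TestPosteriors:
    def test_uniform_model_uniform_posteriors(self, binary_schema):
        p = uniform_parameters(binary_schema, 2)
        traj = Trajectory("s", np.zeros((4, 1), dtype=int))
        gamma, xi = forward_backward_posteriors(p, traj)
        assert np.allclose(gamma, 0.5)
        assert np.allclose(xi, 0.25)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_and_normalizes(self, trial, two_channel_schema):
        rng = np.random.default_rng(2000 + trial)
        S = int(rng.integers(2, 4))
        L = int(rng.integers(2, 6))
        p = random_model(two_channel_schema, S, rng)
        traj = Trajectory(
            "s",
            rng.integers(0, [2, 3], size=(L, 2)),
            rng.integers(0, 2, size=(L, 1)),
        )
        gamma, xi = forward_backward_posteriors(p, traj)
        g_ref, xi_ref = brute_force_posteriors(p, traj)
        assert np.allclose(gamma, g_ref, atol=1e-10)
        assert np.allclose(xi, xi_ref, atol=1e-10)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-10)
        # marginalizing xi over the destination recovers gamma
        assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-10)


# ------------------------------------------------------------------------ EM


class TestFitEM:
    def test_single_state_closed_form(self, binary_schema):
        traj = Trajectory("s", np.array([0] * 7 + [1] * 3).reshape(-1, 1))
        res = fit_em(traj, binary_schema, 1, seed=0)
        probs = softmax(res.params.emission_weights[0][0, :, 0])
        assert np.allclose(probs, [0.7, 0.3], atol=1e-8)
        assert res.converged

    @pytest.mark.parametrize("use_cov", [False, True])
    def test_monotone_trace(self, use_cov, two_channel_schema):
        rng = np.random.default_rng(3)
        gen = random_model(two_channel_schema, 2, rng)
        cov = rng.integers(0, 2, size=(30, 1))
        traj = sample_trajectory(gen, cov, seed=11)
        cfg = EMConfig(use_covariates_in_transitions=use_cov)
        res = fit_em(traj, two_channel_schema, 2, config=cfg, seed=5)
        diffs = np.diff(res.log_likelihood_trace)
        assert (diffs >= -1e-8).all()

    def test_overfitting_guard(self, binary_schema):
        traj = Trajectory("s", np.zeros((2, 1), dtype=int))
        with pytest.raises(OverfitError):
            fit_em(traj, binary_schema, 3, seed=0)

    def test_n_free_parameters(self, two_channel_schema):
        # S=2, p=1: init 1, transitions 2*1*(1+1)=4, emissions 2*(1+2)=6
        assert (
            n_free_parameters(two_channel_schema, 2, True, False) == 1 + 4 + 2 * 1 + 2 * 2
        )

    def test_multi_state_needs_length_two(self, binary_schema):
        traj = Trajectory("s", np.zeros((1, 1), dtype=int))
        with pytest.raises(TrajectoryError):
            fit_em(traj, binary_schema, 2, seed=0)


def _recovery_model():
    schema = DatasetSchema(
        observation_channels=tuple((f"c{i}", ("A", "B")) for i in range(3))
    )
    A = np.array([[0.97, 0.03], [0.03, 0.97]])
    Es = [
        np.array([[0.98, 0.02], [0.02, 0.98]]),
        np.array([[0.97, 0.03], [0.03, 0.97]]),
        np.array([[0.02, 0.98], [0.98, 0.02]]),
    ]
    model = model_from_tables(schema, [0.5, 0.5], A, Es)
    return schema, model, A, Es


@pytest.mark.parametrize("seed", range(7, 17))
def test_two_state_parameter_recovery(seed):
    """Refitting one length-500 sampled series recovers the generator within
    0.05 after the best label permutation."""
    schema, model, A, Es = _recovery_model()
    traj = sample_trajectory(model, np.zeros((500, 0)), seed=seed)
    cfg = EMConfig(use_covariates_in_transitions=False)
    res = fit_em(traj, schema, 2, config=cfg, seed=10_000 + seed)
    Ah = softmax(res.params.transition_weights[:, :, 0], axis=1)
    Ehs = [softmax(w[:, :, 0], axis=1) for w in res.params.emission_weights]
    err = min(
        max(
            [np.abs(Ah[np.ix_(perm, perm)] - A).max()]
            + [np.abs(Eh[perm, :] - E).max() for Eh, E in zip(Ehs, Es)]
        )
        for perm in ([0, 1], [1, 0])
    )
    assert err < 0.05


# ------------------------------------------------------------------ sampling


class TestSampling:
    def test_deterministic_model_forces_sequence(self, binary_schema):
        eps = 1e-9
        m = model_from_tables(
            binary_schema,
            initial=[1 - eps, eps],
            transition=[[eps, 1 - eps], [1 - eps, eps]],  # alternate states
            emissions=[np.array([[1 - eps, eps], [eps, 1 - eps]])],
        )
        traj = sample_trajectory(m, np.zeros((6, 0)), seed=0)
        assert traj.observations[:, 0].tolist() == [0, 1, 0, 1, 0, 1]

    def test_empirical_emission_frequency(self, binary_schema):
        m = model_from_tables(
            binary_schema,
            initial=[1.0],
            transition=[[1.0]],
            emissions=[np.array([[0.7, 0.3]])],
        )
        rng = np.random.default_rng(0)
        draws = [
            sample_trajectory(m, np.zeros((1, 0)), seed=rng).observations[0, 0]
            for _ in range(10_000)
        ]
        assert np.isclose(np.mean(np.array(draws) == 0), 0.7, atol=0.02)

    def test_same_seed_reproducible(self, two_channel_schema):
        rng = np.random.default_rng(2)
        m = random_model(two_channel_schema, 2, rng)
        cov = rng.integers(0, 2, size=(12, 1))
        t1 = sample_trajectory(m, cov, seed=99)
        t2 = sample_trajectory(m, cov, seed=99)
        assert np.array_equal(t1.observations, t2.observations)


def test_forward_matches_hmmlearn_reference(binary_schema):
    """Cross-check the forward algorithm against hmmlearn on a
    covariate-free categorical model."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    A = np.array([[0.8, 0.2], [0.3, 0.7]])
    E = np.array([[0.9, 0.1], [0.25, 0.75]])
    pi = np.array([0.6, 0.4])
    m = model_from_tables(binary_schema, pi, A, [E])
    ref = hmmlearn.CategoricalHMM(n_components=2)
    ref.startprob_ = pi
    ref.transmat_ = A
    ref.emissionprob_ = E
    rng = np.random.default_rng(4)
    for _ in range(5):
        obs = rng.integers(0, 2, size=(8, 1))
        ours = forward_log_likelihood(m, Trajectory("s", obs))
        theirs = ref.score(obs)
        assert np.isclose(ours, theirs, atol=1e-8)
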