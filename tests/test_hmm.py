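"""HMM engine: oracle equivalence, EM contracts, recovery, comparator."""

import numpy as np
import pytest

from conftest import brute_force_loglik, brute_force_viterbi, random_hmm_instance, sample_hmm

from cellpheno.errors import InitializationError
from cellpheno.hmm import (
    FrozenMixture,
    GaussianCycleHMM,
    baum_welch,
    gmm_comparator,
    init_from_cycle,
    marginal_loglik,
    refit_transitions,
    viterbi,
)


def toy_model(pi, A, means, covs):
    m = GaussianCycleHMM(n_states=len(pi))
    m.startprob_ = np.asarray(pi, dtype=float)
    m.transmat_ = np.asarray(A, dtype=float)
    m.means_ = np.asarray(means, dtype=float)
    m.covars_ = np.asarray(covs, dtype=float)
    m.n_states_ = len(pi)
    return m


class TestOracleEquivalence:
    """Forward likelihood and Viterbi vs exhaustive enumeration."""

    @pytest.mark.parametrize("case", range(25))
    def test_forward_and_viterbi_match_enumeration(self, case):
        rng = np.random.default_rng(100 + case)
        pi, A, means, covs, seq = random_hmm_instance(rng)
        model = toy_model(pi, A, means, covs)
        assert marginal_loglik(model, seq) == pytest.approx(
            brute_force_loglik(pi, A, means, covs, seq), abs=1e-8
        )
        oracle_path, oracle_lp = brute_force_viterbi(pi, A, means, covs, seq)
        path = viterbi(model, seq)
        np.testing.assert_array_equal(path.states, oracle_path)
        assert path.log_prob == pytest.approx(oracle_lp, abs=1e-8)

    def test_forward_matches_independent_implementation_on_long_sequences(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(7)
        N, k = 4, 3
        pi = rng.dirichlet(np.ones(N))
        A = rng.dirichlet(np.ones(N), size=N)
        means = rng.normal(scale=3.0, size=(N, k))
        covs = np.array([np.diag(rng.uniform(0.5, 2.0, k)) for _ in range(N)])
        seq = rng.normal(scale=2.0, size=(90, k))

        ref = hmmlearn.GaussianHMM(n_components=N, covariance_type="full", init_params="")
        ref.startprob_, ref.transmat_, ref.means_, ref.covars_ = pi, A, means, covs
        model = toy_model(pi, A, means, covs)
        assert model.score(seq) == pytest.approx(ref.score(seq), abs=1e-6)
        np.testing.assert_array_equal(model.decode(seq)[1], ref.predict(seq))

    def test_single_frame_closed_form(self):
        rng = np.random.default_rng(3)
        pi, A, means, covs, _ = random_hmm_instance(rng, max_states=3, max_T=1)
        from scipy.special import logsumexp
        from scipy.stats import multivariate_normal

        x = rng.normal(size=(1, means.shape[1]))
        model = toy_model(pi, A, means, covs)
        expected = logsumexp(
            [np.log(pi[j]) + multivariate_normal.logpdf(x[0], means[j], covs[j]) for j in range(len(pi))]
        )
        assert marginal_loglik(model, x) == pytest.approx(expected, abs=1e-10)

    def test_loglik_additive_over_sequences(self):
        rng = np.random.default_rng(4)
        pi, A, means, covs, seq = random_hmm_instance(rng, max_states=3, max_T=8)
        model = toy_model(pi, A, means, covs)
        one = marginal_loglik(model, seq)
        both = model.score(np.vstack([seq, seq]), lengths=[len(seq), len(seq)])
        assert both == pytest.approx(2 * one, rel=1e-12)


class TestViterbiContracts:
    def test_identity_transitions_freeze_initial_state(self):
        rng = np.random.default_rng(5)
        means = np.array([[0.0], [4.0]])
        covs = np.array([np.eye(1), np.eye(1)])
        model = toy_model([1.0, 0.0], np.eye(2), means, covs)
        seq = rng.normal(loc=4.0, size=(10, 1))  # pulls toward state 1, but A forbids it
        path = viterbi(model, seq)
        assert np.all(path.states == 0)

    def test_identical_emissions_tie_break_to_lowest_state(self):
        means = np.zeros((3, 2))
        covs = np.array([np.eye(2)] * 3)
        model = toy_model(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), means, covs)
        seq = np.random.default_rng(0).normal(size=(6, 2))
        assert np.all(viterbi(model, seq).states == 0)


class TestCycleInit:
    def test_bin_moments_recovered(self):
        rng = np.random.default_rng(8)
        N, k, n_per = 6, 3, 600
        true_means = rng.normal(scale=5.0, size=(N, k))
        X = np.concatenate([true_means[j] + rng.standard_normal((n_per, k)) for j in range(N)])
        bins = np.repeat(np.arange(N), n_per)
        model = init_from_cycle(X, bins, N=N, ridge=0.0)
        se = 1.0 / np.sqrt(n_per)
        assert np.all(np.abs(model.means_ - true_means) < 3 * se)
        assert np.allclose(model.transmat_, 1 / N) and np.allclose(model.startprob_, 1 / N)

    def test_single_state_is_global_moments(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(500, 2))
        model = init_from_cycle(X, np.zeros(500, dtype=int), N=1, ridge=0.0)
        np.testing.assert_allclose(model.means_[0], X.mean(axis=0))
        np.testing.assert_allclose(model.covars_[0], np.cov(X, rowvar=False, ddof=0), atol=1e-12)
        np.testing.assert_array_equal(model.transmat_, [[1.0]])

    def test_empty_bin_strict_raises_naming_bin(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        bins = np.random.default_rng(1).integers(0, 4, size=100)  # bins 4, 5 empty
        with pytest.raises(InitializationError, match="4"):
            init_from_cycle(X, bins, N=6, strict=True)

    def test_empty_bin_merged_with_warning(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        bins = np.random.default_rng(1).integers(0, 4, size=100)
        with pytest.warns(UserWarning, match="merged"):
            model = init_from_cycle(X, bins, N=6)
        assert model.n_states_ == 4


class TestBaumWelch:
    def test_two_state_parameter_recovery(self):
        rng = np.random.default_rng(12)
        pi = np.array([0.6, 0.4])
        A = np.array([[0.85, 0.15], [0.25, 0.75]])
        means = np.array([[0.0, 0.0], [3.0, -3.0]])
        covs = np.array([np.eye(2), np.eye(2)])
        seqs = [sample_hmm(rng, pi, A, means, covs, 50)[0] for _ in range(200)]

        init = toy_model([0.5, 0.5], np.full((2, 2), 0.5), means + rng.normal(scale=0.3, size=(2, 2)), covs)
        init.ridge = 0.0
        fitted = baum_welch(init, seqs)
        # match learned states to the generator by mean proximity
        perm = np.argmin(
            np.linalg.norm(fitted.means_[:, None, :] - means[None, :, :], axis=2), axis=1
        )
        A_hat = fitted.transmat_[np.ix_(np.argsort(perm), np.argsort(perm))]
        assert np.all(np.abs(A_hat - A) < 0.05)

    def test_training_loglik_nondecreasing(self):
        rng = np.random.default_rng(13)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        means = np.array([[0.0], [2.5]])
        covs = np.array([np.eye(1), np.eye(1)])
        seqs = [sample_hmm(rng, pi, A, means, covs, 40)[0] for _ in range(30)]
        init = toy_model(pi, A, means + 0.5, covs)
        init.ridge = 0.08
        fitted = baum_welch(init, seqs)
        diffs = np.diff(fitted.history_)
        assert np.all(diffs > -1e-6)

    def test_ridge_keeps_covariance_positive_definite_on_degenerate_data(self):
        seq = np.tile([1.0, 2.0], (30, 1))  # one repeated point
        model = GaussianCycleHMM(n_states=2, ridge=0.08, max_iter=10)
        model.initialize_from_cycle(
            np.vstack([seq, seq + 0.5]), np.repeat([0, 1], 30)
        )
        model.fit(seq)
        eigvals = np.linalg.eigvalsh(model.covars_)
        assert np.all(eigvals >= 0.08 - 1e-8)

    def test_max_iter_zero_returns_init_with_one_evaluation(self):
        rng = np.random.default_rng(14)
        pi, A, means, covs, seq = random_hmm_instance(rng, max_states=2, max_T=8)
        model = toy_model(pi, A, means, covs)
        model.ridge = 0.0
        out = baum_welch(model, [seq], max_iter=0)
        np.testing.assert_array_equal(out.transmat_, A)
        np.testing.assert_array_equal(out.means_, means)
        assert len(out.history_) == 1

    def test_row_stochasticity_preserved(self):
        rng = np.random.default_rng(15)
        pi = np.full(3, 1 / 3)
        A = rng.dirichlet(np.ones(3), size=3)
        means = rng.normal(scale=3, size=(3, 2))
        covs = np.array([np.eye(2)] * 3)
        seqs = [sample_hmm(rng, pi, A, means, covs, 30)[0] for _ in range(20)]
        fitted = baum_welch(toy_model(pi, A, means, covs), seqs)
        np.testing.assert_allclose(fitted.transmat_.sum(axis=1), 1.0, atol=1e-10)
        assert fitted.startprob_.sum() == pytest.approx(1.0, abs=1e-10)


class TestRefitTransitions:
    def test_fixed_point_on_training_data(self):
        rng = np.random.default_rng(16)
        pi = np.array([0.5, 0.5])
        A = np.array([[0.9, 0.1], [0.3, 0.7]])
        means = np.array([[0.0], [4.0]])
        covs = np.array([np.eye(1), np.eye(1)])
        seqs = [sample_hmm(rng, pi, A, means, covs, 60)[0] for _ in range(50)]
        converged = baum_welch(toy_model(pi, A, means, covs), seqs)
        refit = refit_transitions(converged, seqs)
        assert np.all(np.abs(refit.transmat_ - converged.transmat_) < 1e-3)

    def test_recovers_swapped_transition_matrix_with_frozen_emissions(self):
        rng = np.random.default_rng(17)
        means = np.array([[0.0, 0.0], [4.0, -4.0]])
        covs = np.array([np.eye(2), np.eye(2)])
        A_prime = np.array([[0.6, 0.4], [0.5, 0.5]])
        pi = np.array([0.5, 0.5])
        seqs = [sample_hmm(rng, pi, A_prime, means, covs, 60)[0] for _ in range(80)]
        model = toy_model(pi, np.array([[0.9, 0.1], [0.1, 0.9]]), means, covs)
        refit = refit_transitions(model, seqs)
        assert np.all(np.abs(refit.transmat_ - A_prime) < 0.05)
        np.testing.assert_array_equal(refit.means_, model.means_)
        np.testing.assert_array_equal(refit.covars_, model.covars_)


class TestGmmComparator:
    def test_data_from_one_component_concentrates_weight(self):
        rng = np.random.default_rng(18)
        means = np.array([[0.0, 0.0], [8.0, 8.0]])
        covs = np.array([np.eye(2), np.eye(2)])
        model = toy_model([0.5, 0.5], np.full((2, 2), 0.5), means, covs)
        X = rng.multivariate_normal(means[0], covs[0], size=500)
        gmm = gmm_comparator(model, X)
        assert gmm.weights_[0] > 0.99

    def test_identical_components_keep_uniform_weights(self):
        means = np.zeros((3, 2))
        covs = np.array([np.eye(2)] * 3)
        model = toy_model(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), means, covs)
        gmm = gmm_comparator(model, np.random.default_rng(0).normal(size=(200, 2)))
        np.testing.assert_allclose(gmm.weights_, 1 / 3, atol=1e-10)

    def test_weights_are_a_probability_vector(self):
        rng = np.random.default_rng(19)
        means = rng.normal(size=(4, 2))
        covs = np.array([np.eye(2)] * 4)
        model = toy_model(np.full(4, 0.25), np.full((4, 4), 0.25), means, covs)
        gmm = gmm_comparator(model, rng.normal(size=(300, 2)))
        assert gmm.weights_.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(gmm.weights_ >= 0)
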