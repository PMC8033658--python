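"""Forward-backward oracles, EM behavior, criteria, grid search, bands."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from lmtraject.latent_markov import (
    DegenerateDataError,
    LatentModel,
    count_free_parameters,
    derive_state_bands,
    em_fit,
    forward_backward,
    information_criteria,
    pool_models,
    select_states,
    state_log_density,
)
from conftest import brute_force_loglik, random_model


def two_state_model():
    return LatentModel(
        r=2, initial=[0.3, 0.7], transition=[[0.8, 0.2], [0.4, 0.6]],
        emission_means=[40.0, 60.0], emission_sds=[10.0, 10.0],
    )


class TestStateLogDensity:
    def test_density_at_the_mean(self):
        m = two_state_model()
        v = state_log_density(40.0, m)
        assert v[0] == pytest.approx(-math.log(10.0 * math.sqrt(2 * math.pi)))

    def test_missing_score_marginalizes_to_log_one(self):
        np.testing.assert_array_equal(state_log_density(float("nan"),
                                                        two_state_model()), 0.0)

    def test_equidistant_symmetric_scores_tie(self):
        v = state_log_density(50.0, two_state_model())
        assert v[0] == pytest.approx(v[1])


class TestForwardBackward:
    def test_matches_brute_force_enumeration(self):
        # 100 random (model, sequence) pairs, r <= 3, T <= 5
        rng = np.random.default_rng(42)
        for _ in range(100):
            r = int(rng.integers(1, 4))
            t = int(rng.integers(1, 6))
            model = random_model(rng, r)
            y = rng.uniform(0, 100, size=t)
            if t > 1 and rng.random() < 0.3:
                y[rng.integers(0, t)] = np.nan
            post = forward_backward(y, model)
            assert post.loglik == pytest.approx(brute_force_loglik(y, model),
                                                abs=1e-8)

    def test_single_state_chain_degenerates_to_iid_gaussian(self):
        model = LatentModel(r=1, initial=[1.0], transition=[[1.0]],
                            emission_means=[50.0], emission_sds=[8.0])
        y = np.array([45.0, 55.0, 60.0])
        post = forward_backward(y, model)
        expected = norm.logpdf(y, 50.0, 8.0).sum()
        assert post.loglik == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(post.gamma, 1.0)

    def test_all_missing_sequence_returns_prior_marginals(self):
        model = two_state_model()
        y = np.full(4, np.nan)
        post = forward_backward(y, model)
        assert post.loglik == pytest.approx(0.0, abs=1e-12)
        marg = np.array(model.initial)
        for t in range(4):
            np.testing.assert_allclose(post.gamma[t], marg, atol=1e-12)
            marg = marg @ model.transition

    def test_posterior_normalization(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            model = random_model(rng, int(rng.integers(2, 5)))
            y = rng.uniform(0, 100, size=6)
            post = forward_backward(y, model)
            np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)
            np.testing.assert_allclose(post.xi.sum(axis=(1, 2)), 1.0, atol=1e-8)
            np.testing.assert_allclose(post.xi.sum(axis=2), post.gamma[:-1],
                                       atol=1e-8)

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ValueError):
            forward_backward([50.0, float("inf")], two_state_model())


class TestEmFit:
    def test_one_state_recovers_pooled_mle(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(30, 80, size=(25, 6))
        fit = em_fit(scores, r=1, seed=0)
        assert fit.model.emission_means[0] == pytest.approx(scores.mean(), abs=1e-6)
        assert fit.model.emission_sds[0] == pytest.approx(scores.std(), abs=1e-6)

    def test_loglik_nondecreasing_across_iterations(self, fitted4):
        path = np.array(fitted4.loglik_path)
        assert (np.diff(path) >= -1e-8).all()

    def test_parameter_recovery_on_synthetic_cohort(self, truth):
        data, _ = generate_cohort_for_recovery(truth, seed=21)
        fit = em_fit(data, r=4, seed=1)
        assert np.abs(fit.model.emission_means - truth.emission_means).max() < 1.5
        assert np.abs(fit.model.transition - truth.transition).max() < 0.06

    def test_states_relabeled_ascending_by_mean(self, fitted4):
        assert (np.diff(fitted4.model.emission_means) > 0).all()

    def test_ic_field_equalities_exact(self, fitted4):
        assert fitted4.aic == -2.0 * fitted4.loglik + 2.0 * fitted4.n_params
        assert fitted4.bic == -2.0 * fitted4.loglik + math.log(fitted4.n_obs) * fitted4.n_params

    def test_degenerate_request_raises(self):
        scores = np.full((5, 4), 60.0)
        with pytest.raises(DegenerateDataError):
            em_fit(scores, r=2, seed=0)

    def test_agrees_with_independent_hmm_likelihood(self, complete_cohort, fitted4):
        # cross-check the fitted likelihood with an independent HMM library
        hmm = pytest.importorskip("hmmlearn.hmm")
        data, _ = complete_cohort
        m = fitted4.model
        ref = hmm.GaussianHMM(n_components=m.r, covariance_type="diag",
                              init_params="", params="")
        ref.startprob_ = m.initial
        ref.transmat_ = m.transition
        ref.means_ = m.emission_means[:, None]
        ref.covars_ = (m.emission_sds**2)[:, None]
        x = data.scores.reshape(-1, 1)
        lengths = [data.n_waves] * data.n_subjects
        assert fitted4.loglik == pytest.approx(ref.score(x, lengths), abs=1e-6)


def generate_cohort_for_recovery(truth, seed):
    from lmtraject.synthetic_cohort import generate_cohort

    data, _ = generate_cohort(truth, n_subjects=400, n_waves=10,
                              missing_rate=0.0, seed=seed)
    return data, None


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "loglik,p,n,expected_aic,expected_bic",
        [
            (0.0, 0, 1, 0.0, 0.0),
            (-100.0, 5, 1, 210.0, 200.0),
            (-100.0, 5, math.e**2, 210.0, 210.0),
        ],
    )
    def test_formula_evaluation(self, loglik, p, n, expected_aic, expected_bic):
        aic, bic = information_criteria(loglik, p, n)
        assert aic == pytest.approx(expected_aic)
        assert bic == pytest.approx(expected_bic, abs=1e-9)

    @pytest.mark.parametrize("r,expected", [(1, 2), (4, 23), (6, 47)])
    def test_free_parameter_count(self, r, expected):
        assert count_free_parameters(r) == expected


class TestSelectStates:
    def test_default_grid_is_three_to_six(self, complete_cohort):
        import inspect

        from lmtraject.latent_markov import select_states

        sig = inspect.signature(select_states)
        assert (sig.parameters["r_min"].default,
                sig.parameters["r_max"].default) == (3, 6)

    def test_single_cell_grid(self, complete_cohort):
        data, _ = complete_cohort
        table = select_states(data, r_min=2, r_max=2, seed=0, n_restarts=2)
        assert len(table.rows) == 1 and table.selected_r == 2

    def test_bic_prefers_true_state_count(self, complete_cohort):
        data, _ = complete_cohort
        table = select_states(data, seed=0, n_restarts=3)
        assert table.selected_r == 4


class TestStateBands:
    def test_equal_sd_boundary_is_midpoint(self):
        m = LatentModel(r=2, initial=[0.5, 0.5], transition=np.full((2, 2), 0.5),
                        emission_means=[40.0, 60.0], emission_sds=[7.0, 7.0])
        assert derive_state_bands(m).boundaries[0] == pytest.approx(50.0)

    def test_unequal_sd_boundary_matches_quadratic_root(self):
        mu1, s1, mu2, s2 = 50.0, 5.0, 60.0, 10.0
        m = LatentModel(r=2, initial=[0.5, 0.5], transition=np.full((2, 2), 0.5),
                        emission_means=[mu1, mu2], emission_sds=[s1, s2])
        b = derive_state_bands(m).boundaries[0]
        # independent oracle: solve the density-equality quadratic directly
        coeffs = [1 / s1**2 - 1 / s2**2,
                  -2 * (mu1 / s1**2 - mu2 / s2**2),
                  mu1**2 / s1**2 - mu2**2 / s2**2 - 2 * math.log(s2 / s1)]
        roots = np.roots(coeffs)
        inside = [x.real for x in roots if mu1 < x.real < mu2]
        assert b == pytest.approx(inside[0], abs=1e-10)
        assert norm.pdf(b, mu1, s1) == pytest.approx(norm.pdf(b, mu2, s2), rel=1e-9)

    def test_band_rendering_matches_interval_format(self, truth):
        m = LatentModel(r=4, initial=truth.initial, transition=truth.transition,
                        emission_means=truth.emission_means,
                        emission_sds=truth.emission_sds)
        assert derive_state_bands(m).render() == \
            "[0, 44], (44, 56], (56, 69], (69, 100]"

    def test_unordered_means_rejected(self):
        m = LatentModel(r=2, initial=[0.5, 0.5], transition=np.full((2, 2), 0.5),
                        emission_means=[60.0, 60.0], emission_sds=[5.0, 5.0])
        with pytest.raises(ValueError):
            derive_state_bands(m)


class TestPooling:
    def test_pooled_model_is_average_after_ordering(self):
        a = two_state_model()
        # same model with permuted labels; pooling must align by mean first
        b = LatentModel(r=2, initial=[0.7, 0.3],
                        transition=[[0.6, 0.4], [0.2, 0.8]],
                        emission_means=[60.0, 40.0], emission_sds=[10.0, 10.0])
        pooled = pool_models([a, b])
        np.testing.assert_allclose(pooled.emission_means, [40.0, 60.0])
        np.testing.assert_allclose(pooled.initial, [0.3, 0.7])
        np.testing.assert_allclose(pooled.transition, a.transition)
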