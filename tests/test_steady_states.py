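"""Subject transition matrices, stationary solves, grouping, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lmtraject.latent_markov import LatentModel, forward_backward
from lmtraject.steady_states import (
    SubjectSteadyState,
    assign_group,
    cohort_steady_summary,
    compute_subject_steady_states,
    stationary_distribution,
    subject_transition_matrix,
)
from conftest import random_model


def make_posterior(model, y):
    return forward_backward(np.asarray(y, dtype=float), model)


class TestSubjectTransitionMatrix:
    def test_deterministic_single_transition_with_fallback_rows(self):
        # near-certain path state 0 -> state 1 over two waves
        model = LatentModel(
            r=2, initial=[0.5, 0.5], transition=[[0.5, 0.5], [0.5, 0.5]],
            emission_means=[20.0, 80.0], emission_sds=[1.0, 1.0],
        )
        post = make_posterior(model, [20.0, 80.0])
        a = subject_transition_matrix(post, model, shrinkage=0.0)
        np.testing.assert_allclose(a[0], [0.0, 1.0], atol=1e-10)
        # no expected occupancy in state 1 at wave 1 -> population fallback
        np.testing.assert_allclose(a[1], model.transition[1], atol=1e-10)

    def test_infinite_shrinkage_limit_returns_population_rows(self, fitted4,
                                                              complete_cohort):
        data, _ = complete_cohort
        model = fitted4.model
        post = make_posterior(model, data.scores[0])
        a = subject_transition_matrix(post, model, shrinkage=1e12)
        np.testing.assert_allclose(a, model.transition, atol=1e-9)

    def test_rows_always_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            model = random_model(rng, int(rng.integers(2, 5)))
            y = rng.uniform(0, 100, size=int(rng.integers(2, 8)))
            a = subject_transition_matrix(make_posterior(model, y), model,
                                          shrinkage=0.5)
            np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
            assert (a >= 0).all()

    def test_zero_shrinkage_reproduces_decoded_path_frequencies(self):
        # near-deterministic posteriors: expected counts = path counts
        model = LatentModel(
            r=2, initial=[0.5, 0.5], transition=[[0.5, 0.5], [0.5, 0.5]],
            emission_means=[20.0, 80.0], emission_sds=[0.8, 0.8],
        )
        y = [20.0, 20.0, 80.0, 80.0, 20.0]
        a = subject_transition_matrix(make_posterior(model, y), model, shrinkage=0.0)
        # path 0,0,1,1,0: from 0 -> {0:1, 1:1}; from 1 -> {1:1, 0:1}
        np.testing.assert_allclose(a, [[0.5, 0.5], [0.5, 0.5]], atol=1e-8)


class TestStationaryDistribution:
    def test_identity_returns_start_vector(self):
        start = np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(
            stationary_distribution(np.eye(4), start), start, atol=1e-10
        )

    def test_periodic_flip_yields_half_half(self):
        flip = np.array([[0.0, 1.0], [1.0, 0.0]])
        for start in ([1.0, 0.0], [0.2, 0.8]):
            np.testing.assert_allclose(
                stationary_distribution(flip, np.array(start)), [0.5, 0.5],
                atol=1e-6,
            )

    def test_population_matrix_has_expected_unique_stationary(self, truth):
        # independent oracle: direct solve of pi P = pi with sum constraint
        p = truth.transition
        a = np.vstack([(p.T - np.eye(4))[:3], np.ones(4)])
        b = np.array([0.0, 0.0, 0.0, 1.0])
        oracle = np.linalg.solve(a, b)
        pi = stationary_distribution(p)
        np.testing.assert_allclose(pi, oracle, atol=1e-10)
        assert np.max(np.abs(pi @ p - pi)) < 1e-8

    def test_random_stochastic_matrices_satisfy_fixed_point(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            r = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(r), size=r)
            pi = stationary_distribution(p)
            assert pi.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.max(np.abs(pi @ p - pi)) < 1e-8

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.2], [0.3, 0.7]]))


class TestAssignGroup:
    @pytest.mark.parametrize(
        "pi,group,combined,risk",
        [
            ((0.6, 0.2, 0.1, 0.1), "Novice", "Novice", True),
            ((0.25, 0.25, 0.25, 0.25), "Novice", "Novice", False),
            ((0.0, 0.1, 0.2, 0.7), "Competent", "Competent", False),
            ((0.1, 0.5, 0.2, 0.2), "AdvancedBeginnerI", "AdvancedBeginnerI&II", False),
            ((0.1, 0.2, 0.5, 0.2), "AdvancedBeginnerII", "AdvancedBeginnerI&II", False),
        ],
    )
    def test_argmax_grouping_and_risk_flag(self, pi, group, combined, risk):
        g, c, f = assign_group(np.array(pi), risk_threshold=0.5)
        assert (g, c, f) == (group, combined, risk)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=50)
    def test_group_always_matches_modal_state(self, raw):
        pi = np.array(raw) / np.sum(raw)
        g, _, _ = assign_group(pi)
        from lmtraject.steady_states import state_names

        assert g == state_names(4)[int(np.argmax(pi))]


class TestCohortSummary:
    def test_identical_subjects_average_to_themselves(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        subs = [
            SubjectSteadyState("A", np.eye(4), v, "Competent", "Competent", False),
            SubjectSteadyState("B", np.eye(4), v, "Competent", "Competent", False),
        ]
        s = cohort_steady_summary(subs)
        np.testing.assert_allclose(s.mean_stationary, v)
        assert s.group_counts["Competent"] == 2

    def test_two_extreme_subjects_average(self):
        a = SubjectSteadyState("A", np.eye(4), np.array([1.0, 0, 0, 0]),
                               "Novice", "Novice", True)
        b = SubjectSteadyState("B", np.eye(4), np.array([0.0, 0, 0, 1.0]),
                               "Competent", "Competent", False)
        s = cohort_steady_summary([a, b])
        np.testing.assert_allclose(s.mean_stationary, [0.5, 0, 0, 0.5])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cohort_steady_summary([])

    def test_mean_stationary_tracks_truth_at_scale(self, complete_cohort, fitted4):
        data, record = complete_cohort
        from lmtraject.pipeline import _subject_posteriors

        posts = _subject_posteriors(data, fitted4.model)
        subs = compute_subject_steady_states(data.subject_ids, posts, fitted4.model)
        s = cohort_steady_summary(subs)
        truth_mean = record.steady_truth.mean(axis=0)
        assert np.abs(s.mean_stationary - truth_mean).max() < 0.06


class TestMonotonicity:
    def test_top_band_subject_dominates_bottom_band_subject(self, fitted4):
        model = fitted4.model
        low = np.full(10, 35.0)
        high = np.full(10, 80.0)
        subs = compute_subject_steady_states(
            ["low", "high"],
            [make_posterior(model, low), make_posterior(model, high)],
            model,
        )
        assert subs[1].stationary[-1] >= subs[0].stationary[-1]
        assert subs[0].stationary[0] >= subs[1].stationary[0]
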