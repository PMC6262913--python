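"""Conditional-logit probability, log-likelihood, gradient: analytic cases,
brute-force oracles, and structural invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choicersf import (
    ChoiceData,
    choice_probabilities,
    fit_mle,
    log_likelihood,
    log_likelihood_gradient,
    simulate_choice_data,
    utility,
)
from choicersf.errors import ShapeError
from choicersf.likelihood import log_likelihood_hessian, pointwise_log_likelihood


class TestUtility:
    def test_arithmetic(self):
        assert utility(np.array([1.0, -2.0]), np.array([3.0, 1.0])) == 1.0

    def test_zero_vector(self):
        assert utility(np.array([1.0, -2.0]), np.zeros(2)) == 0.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        b, x, y = rng.standard_normal((3, 4))
        assert utility(b, x + y) == pytest.approx(utility(b, x) + utility(b, y))

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            utility(np.ones(3), np.ones(2))


class TestChoiceProbabilities:
    def test_zero_beta_uniform(self):
        X = np.random.default_rng(1).standard_normal((6, 3))
        p = choice_probabilities(np.zeros(3), X)
        np.testing.assert_allclose(p, np.full(6, 1 / 6), atol=1e-15)

    def test_log2_analytic(self):
        X = np.array([[1.0], [0.0]])
        p = choice_probabilities(np.array([math.log(2.0)]), X)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_within_set_shift_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 3))
        b = rng.standard_normal(3)
        p0 = choice_probabilities(b, X)
        X_shift = X.copy()
        X_shift[:, 1] += 7.3  # same shift for every alternative
        np.testing.assert_allclose(choice_probabilities(b, X_shift), p0, atol=1e-12)

    def test_normalization_and_overflow_guard(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 2)) * 100
        p = choice_probabilities(np.array([50.0, -80.0]), X)
        # naive exponentiation would overflow at these utilities; the guard
        # keeps everything finite and normalized (tiny entries underflow to 0)
        assert np.all(np.isfinite(p))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0) and np.all(p <= 1)
        p_mild = choice_probabilities(np.array([0.5, -0.8]), X / 50)
        assert np.all(p_mild > 0)

    def test_singleton_set_probability_one(self):
        p = choice_probabilities(np.array([1.0]), np.array([[2.0]]))
        assert p[0] == 1.0


class TestLogLikelihood:
    def _analytic_data(self):
        # set 1: single covariate (1, 0), beta = ln 2 -> P(chosen=0) = 2/3
        # set 2: equal utilities -> P = 1/2
        X = np.array([[[1.0], [0.0]], [[4.0], [4.0]]])
        return ChoiceData("a", X, np.array([0, 0]), ["v"])

    def test_analytic_composition(self):
        ll, pw = log_likelihood(np.array([math.log(2.0)]), self._analytic_data())
        assert ll == pytest.approx(math.log(2 / 3) + math.log(1 / 2), abs=1e-12)
        np.testing.assert_allclose(pw, [math.log(2 / 3), math.log(1 / 2)], atol=1e-12)

    def test_duplication_doubles(self):
        data = simulate_choice_data([0.5, -0.3], 40, seed=4)
        doubled = ChoiceData(
            "d", np.concatenate([data.X, data.X]), np.concatenate([data.chosen, data.chosen]),
            data.column_names,
        )
        b = np.array([0.2, 0.9])
        assert log_likelihood(b, doubled)[0] == pytest.approx(2 * log_likelihood(b, data)[0])

    def test_matches_brute_force_oracle(self):
        data = simulate_choice_data([1.0, -0.5, 0.25], 50, seed=5)
        b = np.array([0.3, -0.7, 1.1])
        # naive per-set exponentiation oracle
        expected = 0.0
        for i in range(data.n_sets):
            num = math.exp(float(data.X[i, data.chosen[i]] @ b))
            den = sum(math.exp(float(data.X[i, c] @ b)) for c in range(data.n_alternatives))
            expected += math.log(num / den)
        assert log_likelihood(b, data)[0] == pytest.approx(expected, abs=1e-9)

    def test_pointwise_matrix_consistent_with_single_draws(self):
        data = simulate_choice_data([0.4, 0.4], 30, seed=6)
        draws = np.random.default_rng(7).standard_normal((5, 2))
        M = pointwise_log_likelihood(draws, data)
        for s in range(5):
            np.testing.assert_allclose(M[s], log_likelihood(draws[s], data)[1], atol=1e-12)


class TestGradient:
    def test_uniform_case_equals_mean_difference(self):
        data = simulate_choice_data([0.0, 0.0], 25, seed=8)
        g = log_likelihood_gradient(np.zeros(2), data)
        expected = (
            data.X[np.arange(data.n_sets), data.chosen] - data.X.mean(axis=1)
        ).sum(axis=0)
        np.testing.assert_allclose(g, expected, atol=1e-10)

    def test_finite_difference_agreement(self):
        rng = np.random.default_rng(9)
        data = simulate_choice_data([0.5, -1.0, 0.1], 20, seed=10)
        for _ in range(20):
            b = rng.standard_normal(3)
            g = log_likelihood_gradient(b, data)
            eps = 1e-6
            for j in range(3):
                e = np.zeros(3)
                e[j] = eps
                fd = (log_likelihood(b + e, data)[0] - log_likelihood(b - e, data)[0]) / (2 * eps)
                assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_gradient_vanishes_at_mle(self):
        data = simulate_choice_data([1.0, -0.5], 300, seed=11)
        mle = fit_mle(data)
        assert np.linalg.norm(log_likelihood_gradient(mle, data)) < 1e-5

    def test_hessian_negative_definite(self):
        data = simulate_choice_data([0.7, -0.2], 100, seed=12)
        H = log_likelihood_hessian(np.array([0.1, 0.4]), data)
        assert np.all(np.linalg.eigvalsh(H) < 0)


class TestConcavity:
    @settings(max_examples=5, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_optimizer_start_invariance(self, seed):
        """Concave log-likelihood: the optimum is unique regardless of start."""
        data = simulate_choice_data([0.8, -0.4], 200, seed=13)
        rng = np.random.default_rng(seed)
        ref = fit_mle(data)
        alt = fit_mle(data, beta0=rng.uniform(-3, 3, size=2))
        np.testing.assert_allclose(alt, ref, atol=1e-5)
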