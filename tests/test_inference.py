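"""Posterior sampling for one individual: parameter recovery, determinism,
prior-dominated behaviour, MLE agreement, and the chi-square posterior
predictive check."""

import numpy as np
import pytest

from choicersf import (
    ChoiceData,
    FitResult,
    McmcConfig,
    fit_individual,
    fit_mle,
    posterior_predictive_check,
    simulate_choice_data,
)
from choicersf.errors import InvalidConfigError
from choicersf.inference import chi_square_statistic

TRUE_BETA = np.array([1.0, -0.5, 0.25])


@pytest.fixture(scope="module")
def recovery_fit():
    data = simulate_choice_data(TRUE_BETA, 1000, 6, seed=99)
    return data, fit_individual(data, McmcConfig(seed=17))


class TestFitIndividual:
    def test_parameter_recovery_within_three_sd(self, recovery_fit):
        _, fit = recovery_fit
        z = np.abs(fit.posterior_mean - TRUE_BETA) / fit.posterior_sd
        assert np.all(z < 3.0)

    def test_convergence_diagnostics(self, recovery_fit):
        _, fit = recovery_fit
        assert np.all(fit.rhat < 1.1)
        assert np.all(fit.neff > 100)
        assert fit.converged

    def test_draw_shapes_and_pointwise(self, recovery_fit):
        data, fit = recovery_fit
        assert fit.draws.shape == (4, 800, 3)
        assert fit.pointwise.shape == (3200, data.n_sets)

    def test_seeded_determinism(self):
        data = simulate_choice_data([0.5, -0.5], 150, seed=1)
        a = fit_individual(data, McmcConfig(seed=5, n_draws=400, n_burnin=100))
        b = fit_individual(data, McmcConfig(seed=5, n_draws=400, n_burnin=100))
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_prior_dominated_posterior_matches_prior(self):
        """Identical alternatives carry no information: the posterior must
        reproduce the Normal(0, 10) prior."""
        X = np.ones((5, 4, 2))
        data = ChoiceData("null", X, np.zeros(5, dtype=int), ["a", "b"])
        fit = fit_individual(data, McmcConfig(seed=2))
        assert np.all(np.abs(fit.posterior_mean) < 0.5)
        assert np.all(np.abs(fit.posterior_sd - 10.0) / 10.0 < 0.2)

    def test_flat_prior_posterior_mean_matches_mle(self):
        data = simulate_choice_data([0.8, -0.3], 1000, seed=3)
        fit = fit_individual(data, McmcConfig(seed=4, prior_scale=100.0))
        mle = fit_mle(data)
        np.testing.assert_allclose(fit.posterior_mean, mle, atol=3 * fit.posterior_sd.max() / 10)

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            McmcConfig(n_draws=100, n_burnin=200).validate()
        with pytest.raises(InvalidConfigError):
            McmcConfig(n_chains=1).validate()

    def test_save_load_round_trip(self, tmp_path, recovery_fit):
        data, fit = recovery_fit
        fit.save(tmp_path / "fit")
        back = FitResult.load(tmp_path / "fit", data)
        np.testing.assert_allclose(back.draws, fit.draws, atol=1e-10)
        np.testing.assert_allclose(back.rhat, fit.rhat)
        assert back.column_names == fit.column_names


class TestCredibleIntervalCoverage:
    def test_zero_beta_intervals_cover_zero(self):
        """Data simulated at beta = 0: the 95% CI should cover 0 for nearly
        every replicate fit."""
        covered = 0
        reps = 20
        cheap = McmcConfig(n_draws=600, n_burnin=150)
        for r in range(reps):
            data = simulate_choice_data([0.0, 0.0], 300, seed=500 + r)
            fit = fit_individual(data, cheap.replace(seed=r))
            ci = fit.credible_interval()
            covered += int(np.all((ci[:, 0] <= 0) & (0 <= ci[:, 1])))
        assert covered >= 18


class TestPosteriorPredictiveCheck:
    def test_chi_square_statistic_nonnegative_and_analytic(self):
        P = np.array([[0.5, 0.5], [0.25, 0.75]])
        y = np.array([0, 1])
        # set 1: (1-.5)^2/.5 + .5 = 1.0 ; set 2: (1-.75)^2/.75 + .25 = 1/3
        t = chi_square_statistic(y, P)
        assert t == pytest.approx(1.0 + 1.0 / 3.0, abs=1e-12)
        assert t >= 0

    def test_well_specified_fit_not_extreme(self, recovery_fit):
        data, fit = recovery_fit
        p_b = posterior_predictive_check(fit, data, seed=0)
        assert 0.05 < p_b < 0.95

    def test_planted_misfit_detected(self, recovery_fit):
        """Choices forced onto the least-likely alternative produce an
        observed discrepancy far beyond anything the model replicates."""
        data, fit = recovery_fit
        from choicersf.likelihood import all_choice_probabilities

        P = all_choice_probabilities(fit.posterior_mean, data)
        bad = ChoiceData(
            data.individual_id, data.X, np.argmin(P, axis=1), data.column_names
        )
        p_b = posterior_predictive_check(fit, bad, seed=1)
        assert p_b < 0.05

    def test_reps_capped_with_warning(self, recovery_fit):
        data, fit = recovery_fit
        with pytest.warns(UserWarning, match="capped"):
            posterior_predictive_check(fit, data, n_reps=10_000, seed=2)

    def test_p_b_bounds(self, recovery_fit):
        data, fit = recovery_fit
        p_b = posterior_predictive_check(fit, data, n_reps=50, seed=3)
        assert 0.0 <= p_b <= 1.0
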