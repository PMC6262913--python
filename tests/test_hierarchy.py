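"""Hierarchical random-slopes model: hyperparameter recovery, shrinkage,
summaries against quantile oracles, and hyperprior reproduction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from choicersf import (
    ChoiceData,
    McmcConfig,
    fit_individual,
    fit_population,
    shrinkage_report,
    simulate_choice_data,
    summarize_hyperparameters,
)
from choicersf.errors import InvalidConfigError, SchemaError
from choicersf.hierarchy import HyperPosterior


def _population_data(mu, sigma, J, n_sets, seed, C=6, return_betas=False):
    rng = np.random.default_rng(seed)
    out, betas = [], []
    for j in range(J):
        beta_j = rng.normal(mu, sigma)
        betas.append(beta_j)
        out.append(
            simulate_choice_data(
                beta_j, n_sets, C, seed=int(rng.integers(2**31)), individual_id=f"i{j:02d}"
            )
        )
    if return_betas:
        return out, np.array(betas)
    return out


CHEAP = McmcConfig(n_chains=2, n_draws=600, n_burnin=200)


@pytest.fixture(scope="module")
def recovered():
    mu_t, s_t = np.array([0.8, -0.4]), np.array([0.4, 0.2])
    all_data, betas = _population_data(mu_t, s_t, J=12, n_sets=250, seed=0, return_betas=True)
    hp = fit_population(all_data, McmcConfig(seed=1))
    return mu_t, betas, all_data, hp


class TestFitPopulation:
    def test_mu_recovered_within_three_sd(self, recovered):
        mu_t, _, _, hp = recovered
        mu_mean = hp.flat_mu.mean(axis=0)
        mu_sd = hp.flat_mu.std(axis=0, ddof=1)
        assert np.all(np.abs(mu_mean - mu_t) < 3 * mu_sd)

    def test_sigma_tracks_realized_heterogeneity(self, recovered):
        """At small J the likelihood informs the realized between-individual
        spread, so sigma is checked within a factor of two of the sample sd
        of the true random slopes."""
        _, betas, _, hp = recovered
        realized = betas.std(axis=0, ddof=1)
        s_mean = hp.flat_sigma.mean(axis=0)
        assert np.all(s_mean < 2 * realized) and np.all(s_mean > realized / 2)

    def test_sigma_draws_positive(self, recovered):
        *_, hp = recovered
        assert np.all(hp.flat_sigma > 0)

    def test_identical_individuals_shrink_sigma(self):
        """sigma = 0 truth: posterior heterogeneity concentrates near 0."""
        all_data = [
            simulate_choice_data([0.6, -0.6], 400, seed=100 + j, individual_id=f"i{j}")
            for j in range(10)
        ]
        hp = fit_population(all_data, McmcConfig(seed=2))
        assert np.all(np.median(hp.flat_sigma, axis=0) < 0.15)

    def test_seeded_determinism(self):
        all_data = _population_data([0.5], [0.3], J=4, n_sets=80, seed=3)
        a = fit_population(all_data, CHEAP.replace(seed=7))
        b = fit_population(all_data, CHEAP.replace(seed=7))
        np.testing.assert_array_equal(a.mu_draws, b.mu_draws)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)

    def test_single_individual_rejected(self):
        with pytest.raises(InvalidConfigError):
            fit_population([simulate_choice_data([0.1], 50, seed=0)])

    def test_mismatched_columns_rejected(self):
        a = simulate_choice_data([0.1, 0.2], 50, seed=0, individual_id="a")
        b = simulate_choice_data([0.1], 50, seed=1, individual_id="b")
        with pytest.raises(SchemaError):
            fit_population([a, b])


class TestHyperpriorReproduction:
    def test_prior_only_run_reproduces_hyperpriors(self):
        """No-data run: mu draws ~ Normal(0,10), sigma draws ~ Uniform(0,10)
        by Kolmogorov-Smirnov at alpha = 0.01 (draws thinned for dependence)."""
        cfg = McmcConfig(n_chains=4, n_draws=6000, n_burnin=1000, seed=11)
        hp = fit_population(None, cfg, prior_only=True, n_columns=1, n_individuals=4)
        mu = hp.flat_mu[::10, 0]
        sigma = hp.flat_sigma[::10, 0]
        assert len(mu) == 2000
        assert stats.kstest(mu, "norm", args=(0, 10)).pvalue > 0.01
        assert stats.kstest(sigma, "uniform", args=(0, 10)).pvalue > 0.01


def _planted_hp(mu_draws, sigma_draws):
    S, k = mu_draws.shape
    beta = np.zeros((1, S, 2, k))
    ones = np.ones(k)
    return HyperPosterior(
        column_names=[f"v{i}" for i in range(k)],
        individual_ids=["a", "b"],
        mu_draws=mu_draws[None],
        sigma_draws=sigma_draws[None],
        beta_draws=beta,
        rhat_mu=ones, rhat_sigma=ones, neff_mu=ones * 1000, neff_sigma=ones * 1000,
        config=McmcConfig(),
    )


class TestSummaries:
    def test_constant_sigma_shifts_mu_interval(self):
        rng = np.random.default_rng(4)
        mu = rng.normal(0.0, 1.0, size=(4000, 1))
        sigma = np.full((4000, 1), 0.5)
        s = summarize_hyperparameters(_planted_hp(mu, sigma))
        row = s.iloc[0]
        assert row["mu_plus_sigma_lo"] == pytest.approx(row["mu_lo"] + 0.5, abs=1e-9)
        assert row["mu_minus_sigma_hi"] == pytest.approx(row["mu_hi"] - 0.5, abs=1e-9)

    def test_quantile_oracle(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(2.0, 0.3, size=(3000, 1))
        sigma = np.abs(rng.normal(0.5, 0.1, size=(3000, 1)))
        s = summarize_hyperparameters(_planted_hp(mu, sigma)).iloc[0]
        assert s["mu_lo"] == pytest.approx(np.quantile(mu, 0.025), abs=1e-12)
        assert s["mu_hi"] == pytest.approx(np.quantile(mu, 0.975), abs=1e-12)
        assert s["mu_plus_sigma_hi"] == pytest.approx(
            np.quantile(mu + sigma, 0.975), abs=1e-12
        )

    def test_excludes_zero_flags(self):
        mu = np.full((100, 1), 3.0) + np.random.default_rng(6).normal(0, 0.01, (100, 1))
        sigma = np.full((100, 1), 0.5)
        s = summarize_hyperparameters(_planted_hp(mu, sigma)).iloc[0]
        assert bool(s["mu_excludes_zero"])
        assert bool(s["ranef_excludes_zero"])


class TestShrinkage:
    def test_hierarchical_means_closer_to_population_mean(self):
        mu_t, s_t = np.array([0.8]), np.array([0.5])
        all_data = _population_data(mu_t, s_t, J=8, n_sets=120, seed=7)
        hp = fit_population(all_data, CHEAP.replace(seed=8))
        indep = [fit_individual(d, CHEAP.replace(seed=9 + i)) for i, d in enumerate(all_data)]
        rep = shrinkage_report(hp, indep)
        mu_hat = hp.population_mean()[0]
        d_hier = np.abs(rep["hierarchical_mean"] - mu_hat).mean()
        d_indep = np.abs(rep["independent_mean"] - mu_hat).mean()
        assert d_hier <= d_indep + 1e-9

    def test_missing_individual_rejected(self):
        all_data = _population_data([0.3], [0.2], J=3, n_sets=60, seed=10)
        hp = fit_population(all_data, CHEAP.replace(seed=11))
        indep = [fit_individual(all_data[0], CHEAP)]
        with pytest.raises(SchemaError):
            shrinkage_report(hp, indep)
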