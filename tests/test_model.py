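"""Small-area BYM model: Gibbs full conditionals, sampler behaviour,
posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from prevmap import McmcConfig, ModelSpec, fit_bym, summarise_posterior
from prevmap.adjacency import grid_adjacency
from prevmap.model import (FitResult, tau_u_full_conditional,
                           tau_v_full_conditional)
from prevmap.synthetic import simulate_bym_effects


def _simulated_counts(graph, beta0, sigma_u, sigma_v, n_per, seed):
    rng = np.random.default_rng(seed)
    u, v = simulate_bym_effects(graph, sigma_u, sigma_v, rng)
    p = expit(beta0 + u + v)
    n = np.full(graph.n, n_per)
    y = rng.binomial(n_per, p)
    return y, n, p


class TestFullConditionals:
    def test_tau_u_shape_and_rate_analytic(self, grid6):
        spec = ModelSpec(tau_u_shape=1.0, tau_u_rate=0.01)
        rng = np.random.default_rng(0)
        u = rng.standard_normal(36)
        shape, rate = tau_u_full_conditional(spec, grid6, u)
        # connected lattice: rank(Q) = 36 - 1
        assert shape == pytest.approx(1.0 + 35 / 2.0)
        q = grid6.laplacian()
        assert rate == pytest.approx(0.01 + 0.5 * float(u @ q @ u))

    def test_tau_v_shape_and_rate_analytic(self):
        spec = ModelSpec(tau_v_shape=2.0, tau_v_rate=0.5)
        v = np.array([1.0, -2.0, 0.5])
        shape, rate = tau_v_full_conditional(spec, v)
        assert shape == pytest.approx(2.0 + 1.5)
        assert rate == pytest.approx(0.5 + 0.5 * 5.25)


class TestFitBym:
    def test_all_zero_events_posterior_in_unit_interval(self, grid6):
        y = np.zeros(36)
        n = np.full(36, 25)
        fit = fit_bym(y, n, grid6, mcmc=McmcConfig(n_iter=2000, n_burn=500,
                                                   seed=2))
        s = summarise_posterior(fit)
        assert (s["mean"] > 0).all() and (s["mean"] < 0.2).all()

    def test_unobserved_district_has_wider_posterior(self, grid6):
        y, n, _ = _simulated_counts(grid6, -1.0, 0.4, 0.2, 80, seed=4)
        target = 14  # an interior district
        y0, n0 = y.copy(), n.copy()
        y0[target], n0[target] = 0, 0
        mc = McmcConfig(n_iter=4000, n_burn=1000, seed=11)
        s_obs = summarise_posterior(fit_bym(y, n, grid6, mcmc=mc))
        s_un = summarise_posterior(fit_bym(y0, n0, grid6, mcmc=mc))
        assert not s_un.loc[target, "observed"]
        assert s_un.loc[target, "sd"] > s_obs.loc[target, "sd"]

    def test_posterior_sd_shrinks_with_information(self, grid6):
        sds = []
        for n_per in (20, 100, 500):
            y, n, _ = _simulated_counts(grid6, -1.2, 0.3, 0.15, n_per,
                                        seed=9)
            fit = fit_bym(y, n, grid6,
                          mcmc=McmcConfig(n_iter=3000, n_burn=1000, seed=21))
            sds.append(summarise_posterior(fit)["sd"].mean())
        assert sds[0] > sds[1] > sds[2]

    def test_complete_pooling_limit(self, grid6):
        y, n, _ = _simulated_counts(grid6, -1.0, 0.5, 0.3, 100, seed=6)
        # priors forcing the random-effect variances toward zero
        spec = ModelSpec(tau_u_shape=1e4, tau_u_rate=1e-2,
                         tau_v_shape=1e4, tau_v_rate=1e-2)
        fit = fit_bym(y, n, grid6, spec,
                      McmcConfig(n_iter=3000, n_burn=1000, seed=8))
        s = summarise_posterior(fit)
        pooled = y.sum() / n.sum()
        assert s["mean"].std() < 0.01
        assert s["mean"].mean() == pytest.approx(pooled, abs=0.02)

    def test_same_seed_same_summaries(self, grid6):
        y, n, _ = _simulated_counts(grid6, -1.0, 0.3, 0.2, 50, seed=1)
        mc = McmcConfig(n_iter=1500, n_burn=500, seed=77)
        s1 = summarise_posterior(fit_bym(y, n, grid6, mcmc=mc))
        s2 = summarise_posterior(fit_bym(y, n, grid6, mcmc=mc))
        pd.testing.assert_frame_equal(s1, s2)

    def test_covariate_effect_recovered_in_sign(self, grid6):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((36, 1))
        p = expit(-1.0 + 1.2 * x[:, 0])
        n = np.full(36, 200)
        y = rng.binomial(200, p)
        spec = ModelSpec(covariates=x)
        fit = fit_bym(y, n, grid6, spec,
                      McmcConfig(n_iter=3000, n_burn=1000, seed=5))
        assert fit.coef_draws is not None
        assert np.quantile(fit.coef_draws[:, 0], 0.05) > 0.5

    def test_invalid_inputs_rejected(self, grid6):
        n = np.full(36, 10)
        y = n + 1.0
        with pytest.raises(ValueError, match="y > n"):
            fit_bym(y, n, grid6)
        with pytest.raises(ValueError, match="n_iter"):
            fit_bym(np.zeros(36), n, grid6, mcmc=McmcConfig(n_iter=0))
        with pytest.raises(ValueError, match="shape"):
            fit_bym(np.zeros(10), np.ones(10), grid6)


class TestSummaries:
    def _fake_fit(self, p_draws, ids=None):
        k = p_draws.shape[1]
        ids = ids or [str(i) for i in range(k)]
        return FitResult(ids=ids, observed=np.ones(k, dtype=bool),
                         p_draws=p_draws,
                         beta0_draws=np.zeros(p_draws.shape[0]),
                         tau_u_draws=None, tau_v_draws=None, u_draws=None,
                         v_draws=None, coef_draws=None)

    def test_quantiles_match_sorting_oracle(self):
        rng = np.random.default_rng(3)
        draws = rng.beta(2.0, 5.0, size=(997, 3))
        s = summarise_posterior(self._fake_fit(draws))
        for j in range(3):
            srt = np.sort(draws[:, j])
            for q, col in ((0.025, "q2.5"), (0.975, "q97.5")):
                # linear interpolation between order statistics
                pos = (len(srt) - 1) * q
                lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
                oracle = srt[lo] * (1 - frac) + srt[min(lo + 1,
                                                        len(srt) - 1)] * frac
                assert s.loc[j, col] == pytest.approx(oracle, abs=1e-12)

    def test_mean_of_transformed_draws_not_transform_of_mean(self):
        rng = np.random.default_rng(7)
        eta = rng.normal(-2.0, 1.5, size=(5000, 1))  # skewed on p scale
        draws = expit(eta)
        s = summarise_posterior(self._fake_fit(draws))
        assert s.loc[0, "mean"] == pytest.approx(draws.mean(), abs=1e-12)
        assert abs(s.loc[0, "mean"] - expit(eta.mean())) > 0.01

    def test_degenerate_chain_warns_sd_zero(self):
        draws = np.full((100, 1), 0.3)
        with pytest.warns(UserWarning, match="degenerate"):
            s = summarise_posterior(self._fake_fit(draws))
        assert s.loc[0, "sd"] == 0.0

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarise_posterior(self._fake_fit(np.empty((0, 2))))

    def test_interval_ordering(self, grid6):
        y = np.full(36, 5.0)
        n = np.full(36, 40)
        fit = fit_bym(y, n, grid6, mcmc=McmcConfig(n_iter=1500, n_burn=500,
                                                   seed=15))
        s = summarise_posterior(fit)
        assert (s["q2.5"] <= s["mean"]).all()
        assert (s["mean"] <= s["q97.5"]).all()
        assert (s["sd"] > 0).all()
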