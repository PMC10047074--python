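"""Data-cloning engine: cloning semantics, sampler correctness, bands, marginals."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from dcinbreed.diagnostics import gelman_rubin
from dcinbreed.dc import (
    MCMCConfig,
    NotConvergedError,
    clone_dataset,
    confidence_band,
    dc_fit,
    default_grid,
    marginal_loglik,
    prediction_band,
    run_chains,
    wald_ci,
)
from dcinbreed.life_history import MAX_RI_19
from dcinbreed.models import FitnessDataset, ModelSpec, PriorSet, loglik_rows


def ri_dataset(y, A, B, col=None, censored=None):
    n = len(y)
    return FitnessDataset(
        "ri",
        np.asarray(y, float),
        np.zeros(n, bool) if censored is None else np.asarray(censored),
        np.arange(n),
        np.zeros(n) if col is None else np.asarray(col, float),
        np.zeros(n),
        np.zeros(n, np.int64),
        np.array([1980]),
        np.asarray(A, float),
        np.asarray(B, float),
    )


def pinned_beta(F, strength=1e6):
    """(A, B) pinning each latent F_i at a fixed value."""
    F = np.asarray(F, float)
    return strength * F, strength * (1 - F)


QUICK = MCMCConfig(chains=2, iterations=1500, burn_in=700, thin=2, seed=8)


class TestCloneDataset:
    def test_identity_at_one(self):
        d = ri_dataset([0.1, 0.2], [1, 1], [30, 30])
        assert clone_dataset(d, 1) is d

    def test_row_and_latent_growth(self):
        n = 154
        d = ri_dataset(np.full(n, 0.1), np.ones(n), np.full(n, 30.0))
        c = clone_dataset(d, 5)
        assert c.n_rows == 770
        assert c.n_individuals == 5 * n  # each clone draws its own F_i
        # clone blocks address disjoint latent indices
        assert set(c.ind[:n]) == set(range(n))
        assert set(c.ind[n : 2 * n]) == set(range(n, 2 * n))

    def test_invalid_count(self):
        d = ri_dataset([0.1], [1], [30])
        with pytest.raises(ValueError):
            clone_dataset(d, 0)


class TestGelmanRubin:
    def test_identical_chains(self):
        # B = 0, so R-hat is sqrt((n-1)/n), i.e. 1 up to the finite-n factor
        x = np.random.default_rng(0).normal(size=(1, 200))
        chains = np.vstack([x, x])
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)
        assert gelman_rubin(chains) <= 1.0

    def test_same_distribution_below_threshold(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 2000))
        assert gelman_rubin(chains) < 1.1

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(50, 1, 500)])
        assert gelman_rubin(chains) > 5

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 500)) + rng.normal(0, 0.2, size=(4, 1))
        ours = gelman_rubin(chains)
        theirs = az.rhat(az.convert_to_dataset(chains[:, :, None]))["x"].values.item()
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestSampler:
    def test_conjugate_normal_mean(self):
        """Posterior mean/var match the closed form for a normal-mean toy."""
        rng = np.random.default_rng(4)
        n, sigma = 30, 0.01
        y = rng.normal(0.2, sigma, n)
        d = ri_dataset(y, *pinned_beta(np.full(n, 0.5)))
        res = run_chains(ModelSpec("ri", ()), d, PriorSet(), 1, QUICK,
                         fixed={"sigma_r": sigma})
        j = res["param_names"].index("beta0")
        draws = res["draws"][:, :, j].ravel()
        post_var = sigma**2 / n
        se = np.sqrt(2.0 / len(draws)) * post_var * 3  # rough 3 MC SE on the var
        assert draws.mean() == pytest.approx(y.mean(), abs=3 * np.sqrt(post_var / 50))
        assert draws.var(ddof=1) == pytest.approx(post_var, abs=max(se, 0.35 * post_var))

    def test_fixed_seed_reproducible(self):
        d = ri_dataset([0.1, 0.2, 0.15], np.ones(3), np.full(3, 20.0))
        spec = ModelSpec("ri", ())
        cfg = MCMCConfig(chains=2, iterations=300, burn_in=100, seed=42)
        a = run_chains(spec, d, PriorSet(), 2, cfg)
        b = run_chains(spec, d, PriorSet(), 2, cfg)
        assert np.array_equal(a["draws"], b["draws"])

    def test_saved_draw_count(self):
        d = ri_dataset([0.1, 0.2], np.ones(2), np.full(2, 20.0))
        cfg = MCMCConfig(chains=3, iterations=2000, burn_in=1500, thin=5, seed=0)
        res = run_chains(ModelSpec("ri", ()), d, PriorSet(), 1, cfg)
        assert res["draws"].shape == (3, 100, 2)


class TestDCFit:
    def test_ols_match_with_known_covariates(self):
        """With F pinned, the ri regression MLE matches ordinary least squares."""
        rng = np.random.default_rng(9)
        n = 60
        F = rng.uniform(0.0, 0.3, n)
        y = 0.12 + 0.3 * F + rng.normal(0, 0.02, n)
        d = ri_dataset(y, *pinned_beta(F))
        fit = dc_fit(ModelSpec("ri", ("INB",)), d, PriorSet(), (1, 10, 40),
                     config=MCMCConfig(chains=2, iterations=2000, burn_in=1000,
                                       seed=2))
        X = np.column_stack([np.ones(n), F])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.params["beta0"] == pytest.approx(ols[0], abs=0.01)
        assert fit.params["beta1"] == pytest.approx(ols[1], abs=0.01)
        assert fit.converged

    def test_non_identifiable_flagged(self):
        """Confounded intercept and colony effect (col = 1 for everyone)."""
        rng = np.random.default_rng(10)
        n = 40
        y = rng.normal(0.2, 0.02, n)
        d = ri_dataset(y, *pinned_beta(np.full(n, 0.2)), col=np.ones(n))
        spec = ModelSpec("ri", ("INB", "COL"))
        fit = dc_fit(spec, d, PriorSet(), (1, 40),
                     config=MCMCConfig(chains=2, iterations=1500, burn_in=700,
                                       seed=3))
        assert fit.diagnostics.final_scaled_var >= 0.05
        assert not fit.converged

    def test_schedule_must_start_at_one(self):
        d = ri_dataset([0.1], [1.0], [30.0])
        with pytest.raises(ValueError):
            dc_fit(ModelSpec("ri", ()), d, schedule=(5, 40), config=QUICK)


class TestWald:
    def _converged_fit(self):
        rng = np.random.default_rng(5)
        n = 40
        y = rng.normal(0.2, 0.02, n)
        d = ri_dataset(y, *pinned_beta(np.full(n, 0.3)))
        return dc_fit(ModelSpec("ri", ()), d, PriorSet(), (1, 40), config=QUICK)

    def test_interval_arithmetic(self):
        fit = self._converged_fit()
        fit.mle = np.array([0.0, 0.02])
        fit.cov_mle = np.diag([0.01, 1e-6])
        ci = wald_ci(fit)
        assert ci["beta0"][0] == pytest.approx(-0.196, abs=1e-3)
        assert ci["beta0"][1] == pytest.approx(0.196, abs=1e-3)

    def test_higher_level_widens(self):
        fit = self._converged_fit()
        ci95 = wald_ci(fit, 0.95)
        ci99 = wald_ci(fit, 0.99)
        for k in ci95:
            assert ci99[k][0] <= ci95[k][0] and ci99[k][1] >= ci95[k][1]

    def test_refuses_non_converged(self):
        fit = self._converged_fit()
        fit.converged = False
        with pytest.raises(NotConvergedError):
            wald_ci(fit)


class TestMarginalLoglik:
    def test_degenerate_integration_equals_direct_sum(self):
        y = np.array([0.1, 0.2, 0.15])
        F0 = np.array([0.2, 0.1, 0.3])
        d = ri_dataset(y, *pinned_beta(F0, 1e8))
        spec = ModelSpec("ri", ("INB",))
        params = {"beta0": 0.15, "beta1": -0.1, "sigma_r": 0.05}
        direct = loglik_rows(spec, d, params, F0).sum()
        assert marginal_loglik(spec, d, params) == pytest.approx(direct, abs=1e-4)

    def test_single_individual_brute_force(self):
        from dcinbreed.models import loglik_ri

        d = ri_dataset([0.15], [1.0], [30.0])
        spec = ModelSpec("ri", ("INB",))
        params = {"beta0": 0.19, "beta1": -0.1, "sigma_r": 0.05}
        ml = marginal_loglik(spec, d, params)
        F = np.linspace(1e-9, 1 - 1e-9, 10**6)
        integrand = np.exp(
            loglik_ri(np.array([0.15]), params["beta0"] + params["beta1"] * F, 0.05)
        ) * stats.beta.pdf(F, 1, 30)
        brute = np.log(np.trapezoid(integrand, F))
        assert ml == pytest.approx(brute, abs=1e-6)

    def test_beta_variance_limit_approaches_plug_in(self):
        """Errors-in-variables likelihood -> fixed-covariate likelihood."""
        y = np.array([0.1, 0.2])
        spec = ModelSpec("ri", ("INB",))
        params = {"beta0": 0.15, "beta1": -0.2, "sigma_r": 0.04}
        F0 = np.array([0.1, 0.25])
        plug = loglik_rows(spec, ri_dataset(y, *pinned_beta(F0, 1e10)), params,
                           F0).sum()
        gaps = []
        for strength in (1e2, 1e4, 1e6):
            d = ri_dataset(y, *pinned_beta(F0, strength))
            gaps.append(abs(marginal_loglik(spec, d, params) - plug))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3

    def test_nested_model_dominated_by_richer(self):
        """At their own (polished) MLEs, a richer model's marginal log-likelihood
        is at least the nested model's."""
        rng = np.random.default_rng(6)
        n = 50
        F = rng.uniform(0.0, 0.3, n)
        y = np.clip(0.15 - 0.1 * F + rng.normal(0, 0.04, n), 1e-4, MAX_RI_19 - 1e-4)
        A, B = 1 + np.round(29 * F), 30 - np.round(29 * F)
        d = ri_dataset(y, A, B)

        def polished_ll(spec):
            fit = dc_fit(spec, d, PriorSet(), (1, 40), config=QUICK)
            names = spec.param_names

            def neg(v):
                p = dict(zip(names, v))
                if p["sigma_r"] <= 0:
                    return 1e10
                try:
                    return -marginal_loglik(spec, d, p)
                except RuntimeError:
                    return 1e10

            res = minimize(neg, fit.mle, method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
            return -res.fun

        ll_null = polished_ll(ModelSpec("ri", ()))
        ll_inb = polished_ll(ModelSpec("ri", ("INB",)))
        assert ll_inb >= ll_null - 1e-3

    def test_laplace_vs_importance_sampling(self):
        """Year-effect integration: the two marginal approximations agree."""
        rng = np.random.default_rng(7)
        n = 30
        y = np.clip(rng.normal(0.18, 0.05, n), 1e-4, MAX_RI_19 - 1e-4)
        years = np.array([1980, 1981, 1982])
        d = FitnessDataset(
            "ri", y, np.zeros(n, bool), np.arange(n), np.zeros(n), np.zeros(n),
            rng.integers(0, 3, n), years, np.full(n, 2.0), np.full(n, 28.0),
        )
        spec = ModelSpec("ri", ("INB",), year_random_intercept=True)
        params = {"beta0": 0.18, "beta1": -0.05, "sigma_r": 0.05,
                  "sigma_gamma": 0.01}
        lap = marginal_loglik(spec, d, params, year_method="laplace")
        imp = marginal_loglik(spec, d, params, year_method="is", seed=1,
                              n_importance=500)
        assert lap == pytest.approx(imp, abs=0.5)


class TestBands:
    def _fit(self):
        rng = np.random.default_rng(8)
        n = 50
        F = rng.uniform(0.0, 0.3, n)
        y = np.clip(0.15 - 0.1 * F + rng.normal(0, 0.03, n), 1e-4, MAX_RI_19 - 1e-4)
        d = ri_dataset(y, *pinned_beta(F))
        return dc_fit(ModelSpec("ri", ("INB",)), d, PriorSet(), (1, 40),
                      config=QUICK)

    def test_default_grid(self):
        g = default_grid()
        assert len(g) == 1000
        assert 0 < g[0] and g[-1] < 0.25

    def test_zero_covariance_collapses_band(self):
        fit = self._fit()
        fit.cov_mle = np.zeros_like(fit.cov_mle)
        band = confidence_band(fit, default_grid(50), draws=200, seed=0)
        assert np.allclose(band["lower"], band["fit"], atol=1e-12)
        assert np.allclose(band["upper"], band["fit"], atol=1e-12)

    def test_prediction_contains_confidence(self):
        fit = self._fit()
        grid = default_grid(50)
        cb = confidence_band(fit, grid, draws=2000, seed=1)
        pb = prediction_band(fit, grid, seed=1)
        assert np.all(pb["lower"] <= cb["lower"] + 1e-9)
        assert np.all(pb["upper"] >= cb["upper"] - 1e-9)

    def test_prediction_respects_censoring_bound(self):
        fit = self._fit()
        pb = prediction_band(fit, default_grid(20), seed=2)
        assert np.all(pb["upper"] <= MAX_RI_19 + 1e-12)

    def test_band_level_monotone(self):
        fit = self._fit()
        grid = default_grid(20)
        b95 = confidence_band(fit, grid, draws=2000, seed=3, level=0.95)
        b99 = confidence_band(fit, grid, draws=2000, seed=3, level=0.99)
        assert np.all(b99["lower"] <= b95["lower"])
        assert np.all(b99["upper"] >= b95["upper"])
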