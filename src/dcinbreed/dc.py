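"""Data-cloning machinery: cloning, Metropolis-within-Gibbs, diagnostics, MLE.

Data cloning fits a Bayesian hierarchical model to K stacked copies of the
data. As K grows the posterior of the structural parameters collapses onto
the maximum-likelihood estimate, and K times the posterior covariance
converges to the inverse Fisher information, so Wald confidence intervals
come straight from the final clone level. Latent quantities (each
individual's inbreeding coefficient F_i and the birth-year effects) are
replicated per clone; structural parameters (regression coefficients and
scale parameters) are shared.

The sampler is Metropolis-within-Gibbs: scalar random-walk updates for each
structural parameter and vectorized elementwise random-walk updates for the
latent blocks, with proposal scales adapted toward a 20-50% acceptance rate
during burn-in and frozen afterwards. Internally the K clones live on the
leading axis of the latent arrays rather than as physically repeated rows;
:func:`clone_dataset` provides the materialized equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from scipy.optimize import minimize

from .diagnostics import gelman_rubin, normal_fit_statistics
from .life_history import MAX_RI_19
from .models import (
    FitnessDataset,
    ModelSpec,
    PriorSet,
    draw_start_values,
    log_prior,
    loglik_rows,
    survival_from_eta,
    afr_p_from_eta,
    wait_pi_from_eta,
    linear_predictor,
)

DEFAULT_SCHEDULE = (1, 5, 10, 20, 40)


@dataclass
class MCMCConfig:
    chains: int = 3
    iterations: int = 20000
    burn_in: int = 15000
    thin: int = 5
    seed: int = 0
    adapt_until: int | None = None  # defaults to burn_in

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be below iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.adapt_until is None:
            self.adapt_until = self.burn_in
        if self.adapt_until > self.burn_in:
            raise ValueError("adapt_until must not exceed burn_in")


def clone_dataset(data: FitnessDataset, K: int) -> FitnessDataset:
    """Materialize K copies of the data with per-clone latent occupancy.

    Observation rows are tiled K times; each clone's rows point at its own
    block of individual indices (so each clone draws its own F_i), while the
    structural design columns are repeated unchanged.
    """
    if K < 1:
        raise ValueError("clone count must be >= 1")
    if K == 1:
        return data
    n = data.n_individuals
    offs = np.repeat(np.arange(K) * n, data.n_rows)
    return FitnessDataset(
        family=data.family,
        y=np.tile(data.y, K),
        censored=np.tile(data.censored, K),
        ind=np.tile(data.ind, K) + offs,
        col=np.tile(data.col, K),
        first=np.tile(data.first, K),
        year_idx=np.tile(data.year_idx, K),
        year_labels=data.year_labels,
        A=np.tile(data.A, K),
        B=np.tile(data.B, K),
    )


# ---------------------------------------------------------------------------
# Metropolis-within-Gibbs sampler (clones on the leading latent axis)
# ---------------------------------------------------------------------------

class _Context:
    """Precomputed index machinery for one (spec, data, K) sampling problem."""

    def __init__(self, spec: ModelSpec, data: FitnessDataset, K: int):
        self.spec, self.data, self.K = spec, data, K
        n, m, Y = data.n_individuals, data.n_rows, data.n_years
        self.n, self.m, self.Y = n, m, Y
        k_ar = np.arange(K)[:, None]
        self.flat_ind = (k_ar * n + data.ind[None, :]).ravel()
        self.flat_year = (k_ar * Y + data.year_idx[None, :]).ravel()

    def row_ll(self, params, F, gamma, theta) -> np.ndarray:
        d = self.data
        F_row = F[:, d.ind]
        g_row = gamma[:, d.year_idx] if gamma is not None else 0.0
        t_row = theta[:, d.year_idx] if theta is not None else 0.0
        return loglik_rows(self.spec, d, params, F_row, g_row, t_row)

    def by_individual(self, ll: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.flat_ind, weights=ll.ravel(), minlength=self.K * self.n
        ).reshape(self.K, self.n)

    def by_year(self, ll: np.ndarray) -> np.ndarray:
        return np.bincount(
            self.flat_year, weights=ll.ravel(), minlength=self.K * self.Y
        ).reshape(self.K, self.Y)


class _Adapter:
    """Robbins-Monro style proposal-scale adaptation, frozen after a cutoff."""

    def __init__(self, names: list[str], window: int = 50):
        self.scales = {n: 0.1 for n in names}
        self.acc = {n: 0 for n in names}
        self.tries = {n: 0 for n in names}
        self.window = window

    def record(self, name: str, accepted: float, tries: float = 1.0) -> None:
        self.acc[name] += accepted
        self.tries[name] += tries

    def adapt(self) -> None:
        for n in self.scales:
            if self.tries[n] == 0:
                continue
            rate = self.acc[n] / self.tries[n]
            if rate > 0.5:
                self.scales[n] *= 1.4
            elif rate < 0.2:
                self.scales[n] /= 1.4
            self.acc[n] = 0
            self.tries[n] = 0


def _latent_logprior_gamma(g: np.ndarray, sigma: float) -> float:
    return float(-g.size * np.log(sigma) - np.sum(g**2) / (2 * sigma**2))


def _run_single_chain(
    spec: ModelSpec,
    data: FitnessDataset,
    priors: PriorSet,
    K: int,
    config: MCMCConfig,
    seed: int,
    fixed: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    rng = np.random.default_rng(seed)
    ctx = _Context(spec, data, K)
    fixed = fixed or {}
    names = spec.param_names
    free_names = [n for n in names if n not in fixed]
    use_gamma = spec.year_random_intercept
    use_theta = spec.year_random_slope_on_F

    for attempt in range(10):
        params = draw_start_values(spec, rng, priors)
        params.update(fixed)
        F = rng.uniform(0.01, 0.1, size=(K, ctx.n))
        gamma = rng.normal(0.0, 0.1, size=(K, ctx.Y)) if use_gamma else None
        theta = rng.normal(0.0, 0.1, size=(K, ctx.Y)) if use_theta else None
        try:
            cur_rows = ctx.row_ll(params, F, gamma, theta)
        except (ValueError, FloatingPointError):
            continue
        if np.isfinite(cur_rows.sum()) and np.isfinite(log_prior(spec, params, priors)):
            break
    else:
        raise RuntimeError("no finite posterior after 10 starting-value draws")

    adapter = _Adapter(names + ["F", "gamma", "theta"])
    adapter.scales["F"] = 0.05
    lgA, lgB = data.A - 1.0, data.B - 1.0  # Beta prior exponents for F
    cur_lp = log_prior(spec, params, priors)

    n_save = (config.iterations - config.burn_in) // config.thin
    draws = np.empty((n_save, len(names)))
    logpost = np.empty(n_save)
    kept = 0

    for it in range(config.iterations):
        # --- structural scalars ---
        for name in free_names:
            prop = dict(params)
            if name.startswith("sigma"):
                # multiplicative walk: scale parameters span orders of magnitude
                step = adapter.scales[name] * rng.normal()
                prop[name] = params[name] * np.exp(step)
                jacobian = step  # log |d sigma'/d log sigma| difference
            else:
                prop[name] = params[name] + adapter.scales[name] * rng.normal()
                jacobian = 0.0
            lp_prop = log_prior(spec, prop, priors)
            if not np.isfinite(lp_prop):
                adapter.record(name, 0.0)
                continue
            if name in ("sigma_gamma", "sigma_theta") and spec.family != "ri":
                latent = gamma if name == "sigma_gamma" else theta
                delta = (
                    _latent_logprior_gamma(latent, prop[name])
                    - _latent_logprior_gamma(latent, params[name])
                    + lp_prop
                    - cur_lp
                    + jacobian
                )
                prop_rows = None
            elif name == "sigma_gamma":  # ri family: also latent prior
                delta = (
                    _latent_logprior_gamma(gamma, prop[name])
                    - _latent_logprior_gamma(gamma, params[name])
                    + lp_prop
                    - cur_lp
                    + jacobian
                )
                prop_rows = None
            else:
                prop_rows = ctx.row_ll(prop, F, gamma, theta)
                delta = prop_rows.sum() - cur_rows.sum() + lp_prop - cur_lp + jacobian
            if np.log(rng.random()) < delta:
                params = prop
                cur_lp = lp_prop
                if prop_rows is not None:
                    cur_rows = prop_rows
                adapter.record(name, 1.0)
            else:
                adapter.record(name, 0.0)

        # --- latent F block (elementwise, vectorized over clones x individuals) ---
        Fp = F + adapter.scales["F"] * rng.normal(size=F.shape)
        inside = (Fp > 0.0) & (Fp < 1.0)
        Fp_safe = np.where(inside, Fp, F)
        prop_rows = ctx.row_ll(params, Fp_safe, gamma, theta)
        d_ll = ctx.by_individual(prop_rows) - ctx.by_individual(cur_rows)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_prior = (
                lgA * (np.log(Fp_safe) - np.log(F))
                + lgB * (np.log1p(-Fp_safe) - np.log1p(-F))
            )
        delta = np.where(inside, d_ll + d_prior, -np.inf)
        acc = np.log(rng.random(size=F.shape)) < delta
        F = np.where(acc, Fp_safe, F)
        acc_row = acc[:, data.ind]
        cur_rows = np.where(acc_row, prop_rows, cur_rows)
        adapter.record("F", float(acc.mean()))

        # --- latent year blocks ---
        if use_gamma:
            gp = gamma + adapter.scales["gamma"] * rng.normal(size=gamma.shape)
            prop_rows = ctx.row_ll(params, F, gp, theta)
            d_ll = ctx.by_year(prop_rows) - ctx.by_year(cur_rows)
            sg = params["sigma_gamma"]
            d_prior = (gamma**2 - gp**2) / (2 * sg**2)
            acc = np.log(rng.random(size=gamma.shape)) < d_ll + d_prior
            gamma = np.where(acc, gp, gamma)
            cur_rows = np.where(acc[:, data.year_idx], prop_rows, cur_rows)
            adapter.record("gamma", float(acc.mean()))
        if use_theta:
            tp = theta + adapter.scales["theta"] * rng.normal(size=theta.shape)
            prop_rows = ctx.row_ll(params, F, gamma, tp)
            d_ll = ctx.by_year(prop_rows) - ctx.by_year(cur_rows)
            st = params["sigma_theta"]
            d_prior = (theta**2 - tp**2) / (2 * st**2)
            acc = np.log(rng.random(size=theta.shape)) < d_ll + d_prior
            theta = np.where(acc, tp, theta)
            cur_rows = np.where(acc[:, data.year_idx], prop_rows, cur_rows)
            adapter.record("theta", float(acc.mean()))

        if it < config.adapt_until and (it + 1) % adapter.window == 0:
            adapter.adapt()

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            draws[kept] = [params[nm] for nm in names]
            logpost[kept] = cur_rows.sum() + cur_lp
            kept += 1

    return draws, logpost, {"scales": dict(adapter.scales)}


def run_chains(
    spec: ModelSpec,
    data: FitnessDataset,
    priors: PriorSet,
    K: int,
    config: MCMCConfig,
    fixed: dict[str, float] | None = None,
) -> dict:
    """Run ``config.chains`` chains at clone level K; return thinned draws.

    Returns a dict with ``draws`` (chains, saved, P), ``logpost``,
    ``param_names`` and per-chain sampler info. ``fixed`` pins named
    structural parameters at given values (they are recorded but not updated).
    """
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=config.chains)
    out, lp, info = [], [], []
    for c in range(config.chains):
        d, l, i = _run_single_chain(
            spec, data, priors, K, config, int(seeds[c]), fixed
        )
        out.append(d)
        lp.append(l)
        info.append(i)
    return {
        "draws": np.stack(out),
        "logpost": np.stack(lp),
        "param_names": spec.param_names,
        "info": info,
    }


# ---------------------------------------------------------------------------
# data-cloning fit
# ---------------------------------------------------------------------------

@dataclass
class DCDiagnostics:
    lambda_max: float
    ms_error: float
    r_squared: float
    scaled_var_by_K: dict[int, float]
    final_scaled_var: float
    slope_log_var_log_K: float


@dataclass
class DCFit:
    spec: ModelSpec
    clone_schedule: tuple[int, ...]
    param_names: list[str]
    mean_by_K: dict[int, np.ndarray]
    cov_by_K: dict[int, np.ndarray]
    mle: np.ndarray
    cov_mle: np.ndarray
    rhat: np.ndarray
    diagnostics: DCDiagnostics
    converged: bool
    mle_mode: np.ndarray | None = None
    draws_final: np.ndarray | None = None

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.mle))

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_mle))


def dc_fit(
    spec: ModelSpec,
    data: FitnessDataset,
    priors: PriorSet | None = None,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    config: MCMCConfig | None = None,
    keep_draws: bool = False,
    fixed: dict[str, float] | None = None,
) -> DCFit:
    """Fit one model across the clone schedule and extract the MLE.

    The MLE is the pooled posterior mean at the largest K; its covariance is
    K_max times the pooled posterior covariance there. Convergence requires
    the final scaled variance (posterior variance at K_max relative to K=1,
    averaged over parameters) below 0.05 and all R-hat below 1.1.
    Non-convergence is a reported state, not an exception.
    """
    priors = priors or PriorSet()
    config = config or MCMCConfig()
    schedule = tuple(schedule)
    if list(schedule) != sorted(set(schedule)) or schedule[0] != 1:
        raise ValueError("clone schedule must be increasing and start at 1")
    P = len(spec.param_names)
    mean_by_K: dict[int, np.ndarray] = {}
    cov_by_K: dict[int, np.ndarray] = {}
    var_by_K: dict[int, np.ndarray] = {}
    rhat = np.full(P, np.nan)
    draws_final = None
    logpost_final = None
    for K in schedule:
        sub = MCMCConfig(
            chains=config.chains,
            iterations=config.iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=config.seed + K,
            adapt_until=config.adapt_until,
        )
        res = run_chains(spec, data, priors, K, sub, fixed)
        pooled = res["draws"].reshape(-1, P)
        mean_by_K[K] = pooled.mean(axis=0)
        cov_by_K[K] = np.atleast_2d(np.cov(pooled.T))
        var_by_K[K] = pooled.var(axis=0, ddof=1)
        if K == schedule[-1]:
            rhat = gelman_rubin(res["draws"])
            draws_final = res["draws"]
            logpost_final = res["logpost"]
    base = var_by_K[schedule[0]]
    free = np.array([nm not in (fixed or {}) for nm in spec.param_names])
    free &= base > 0  # guard against degenerate posteriors
    scaled = {K: float(np.mean(v[free] / base[free])) for K, v in var_by_K.items()}
    ks = np.array(schedule, dtype=float)
    sv = np.array([scaled[K] for K in schedule])
    if len(schedule) > 1:
        slope = float(np.polyfit(np.log(ks), np.log(np.maximum(sv, 1e-300)), 1)[0])
    else:
        slope = float("nan")
    K_max = schedule[-1]
    pooled_final = draws_final.reshape(-1, P)
    ms_error, r2 = normal_fit_statistics(pooled_final)
    lam_max = float(np.linalg.eigvalsh(cov_by_K[K_max])[-1])
    diag = DCDiagnostics(
        lambda_max=lam_max,
        ms_error=ms_error,
        r_squared=r2,
        scaled_var_by_K=scaled,
        final_scaled_var=scaled[K_max],
        slope_log_var_log_K=slope,
    )
    converged = bool(scaled[K_max] < 0.05 and np.all(rhat < 1.1))
    flat_best = int(np.argmax(logpost_final.ravel()))
    return DCFit(
        spec=spec,
        clone_schedule=schedule,
        param_names=spec.param_names,
        mean_by_K=mean_by_K,
        cov_by_K=cov_by_K,
        mle=mean_by_K[K_max],
        cov_mle=K_max * cov_by_K[K_max],
        rhat=np.atleast_1d(rhat),
        diagnostics=diag,
        converged=converged,
        mle_mode=pooled_final[flat_best],
        draws_final=draws_final if keep_draws else None,
    )


class NotConvergedError(RuntimeError):
    pass


def wald_ci(fit: DCFit, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """MLE +/- z * sqrt(diag(cov_mle)); refuses a non-converged fit."""
    if not fit.converged:
        raise NotConvergedError(
            "Wald intervals are only valid for a data-cloning fit whose "
            "posterior has collapsed to the normal ML approximation; this "
            "fit did not converge"
        )
    z = stats.norm.ppf(0.5 + level / 2)
    se = fit.se()
    return {
        name: (float(fit.mle[j] - z * se[j]), float(fit.mle[j] + z * se[j]))
        for j, name in enumerate(fit.param_names)
    }


# ---------------------------------------------------------------------------
# marginal likelihood (latents integrated out)
# ---------------------------------------------------------------------------

_jacobi_cache: dict[tuple[float, float, int], tuple[np.ndarray, np.ndarray]] = {}

#: above this A+B the Jacobi recurrence is numerically unreliable; the Beta is
#: then narrow enough for the quantile-transform route
_JACOBI_LIMIT = 600.0


def _beta_quadrature_nodes(
    A: np.ndarray, B: np.ndarray, n_nodes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual quadrature nodes and log-weights for E_Beta(A,B)[g(F)].

    Returns (F_nodes, logW), both (n_nodes, n): ``sum exp(logW) g(F)``
    approximates the Beta-weighted integral column-wise.
    """
    from scipy.special import betaln, roots_jacobi

    n = len(A)
    F = np.empty((n_nodes, n))
    logW = np.empty((n_nodes, n))
    leg_nodes, leg_wts = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (leg_nodes + 1.0)
    log_leg = np.log(0.5 * leg_wts)
    for j in range(n):
        a, b = float(A[j]), float(B[j])
        if a + b <= _JACOBI_LIMIT:
            key = (a, b, n_nodes)
            if key not in _jacobi_cache:
                x, w = roots_jacobi(n_nodes, b - 1.0, a - 1.0)
                logw = (
                    np.log(w) - betaln(a, b) - (a + b - 1.0) * np.log(2.0)
                )
                _jacobi_cache[key] = ((1.0 + x) / 2.0, logw)
            F[:, j], logW[:, j] = _jacobi_cache[key]
        else:
            F[:, j] = np.clip(stats.beta.ppf(u, a, b), 1e-12, 1 - 1e-12)
            logW[:, j] = log_leg
    return F, logW


def _individual_marginal_ll(
    spec: ModelSpec,
    data: FitnessDataset,
    params: dict[str, float],
    n_nodes: int,
    gamma: np.ndarray | None = None,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """log integral over F_i on (0,1) of the per-individual likelihood, per individual.

    The integral against the Beta(A_i, B_i) measurement density uses
    Gauss-Jacobi quadrature with the Jacobi weight matched to the Beta
    exponents, so the measurement density is handled exactly and only the
    smooth likelihood factor is approximated. For very concentrated Betas
    (large A + B), where the Jacobi recurrence loses stability, the integral
    instead substitutes F = Q_i(u) (the Beta quantile function) and applies
    Gauss-Legendre on the probability scale. Conditional on fixed year
    effects.
    """
    F_nodes, logW = _beta_quadrature_nodes(data.A, data.B, n_nodes)  # (G, n) each
    m, n = data.n_rows, data.n_individuals
    g_row = gamma[data.year_idx] if gamma is not None else 0.0
    t_row = theta[data.year_idx] if theta is not None else 0.0
    F_rows = F_nodes[:, data.ind]
    ll = loglik_rows(
        spec,
        data,
        params,
        F_rows,
        np.broadcast_to(g_row, (n_nodes, m)) if gamma is not None else 0.0,
        np.broadcast_to(t_row, (n_nodes, m)) if theta is not None else 0.0,
    )  # (G, m)
    flat = (np.arange(n_nodes)[:, None] * n + data.ind[None, :]).ravel()
    ll_ind = np.bincount(flat, weights=ll.ravel(), minlength=n_nodes * n).reshape(
        n_nodes, n
    )
    return logsumexp(logW + ll_ind, axis=0)


def _fd_hessian(f, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = len(x0)
    H = np.empty((d, d))
    f0 = f(x0)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h * h)
    return H


def marginal_loglik(
    spec: ModelSpec,
    data: FitnessDataset,
    params: dict[str, float],
    n_nodes: int = 64,
    year_method: str = "laplace",
    n_importance: int = 2000,
    seed: int = 0,
    rtol: float = 1e-6,
) -> float:
    """Log-likelihood at ``params`` with all latent quantities integrated out.

    Each F_i is integrated by Gauss-Legendre quadrature on (0,1) with a
    node-doubling convergence check; the birth-year random-effect vector is
    integrated by a Laplace approximation (``year_method='laplace'``) or,
    for validation, by importance sampling from the Laplace proposal
    (``year_method='is'``).
    """
    use_gamma = spec.year_random_intercept
    use_theta = spec.year_random_slope_on_F
    if not use_gamma and not use_theta:
        ll1 = _individual_marginal_ll(spec, data, params, n_nodes).sum()
        ll2 = _individual_marginal_ll(spec, data, params, 2 * n_nodes).sum()
        if abs(ll2 - ll1) > rtol * max(1.0, abs(ll2)):
            raise RuntimeError(
                f"F quadrature did not converge on node doubling: {ll1} vs {ll2}"
            )
        return float(ll2)

    Y = data.n_years
    d = (Y if use_gamma else 0) + (Y if use_theta else 0)

    def unpack(u: np.ndarray):
        k = 0
        g = t = None
        if use_gamma:
            g = u[k : k + Y]; k += Y
        if use_theta:
            t = u[k : k + Y]
        return g, t

    def g_fun(u: np.ndarray) -> float:
        g, t = unpack(u)
        val = _individual_marginal_ll(spec, data, params, n_nodes, g, t).sum()
        if use_gamma:
            val += np.sum(stats.norm.logpdf(g, 0.0, params["sigma_gamma"]))
        if use_theta:
            val += np.sum(stats.norm.logpdf(t, 0.0, params["sigma_theta"]))
        return float(val)

    res = minimize(lambda u: -g_fun(u), np.zeros(d), method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    u_hat = res.x
    H = _fd_hessian(g_fun, u_hat)
    neg_H = -(H + H.T) / 2
    evals = np.linalg.eigvalsh(neg_H)
    if evals.min() <= 0:
        neg_H += (1e-8 - evals.min()) * np.eye(d)
    sign, logdet = np.linalg.slogdet(neg_H)
    laplace = g_fun(u_hat) + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet
    if year_method == "laplace":
        return float(laplace)
    if year_method != "is":
        raise ValueError("year_method must be 'laplace' or 'is'")
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(neg_H)
    us = rng.multivariate_normal(u_hat, cov, size=n_importance)
    logq = stats.multivariate_normal.logpdf(us, u_hat, cov)
    logp = np.array([g_fun(u) for u in us])
    return float(logsumexp(logp - logq) - np.log(n_importance))


# ---------------------------------------------------------------------------
# confidence and prediction bands
# ---------------------------------------------------------------------------

def default_grid(n: int = 1000, lo: float = 0.0, hi: float = 0.25) -> np.ndarray:
    """n equally spaced inbreeding-coefficient values on the open interval (lo, hi)."""
    return np.linspace(lo, hi, n + 2)[1:-1]


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    evals, vecs = np.linalg.eigh((cov + cov.T) / 2)
    if evals.min() >= 0:
        return cov
    warnings.warn("covariance not PSD; clipping negative eigenvalues")
    return (vecs * np.clip(evals, 1e-12, None)) @ vecs.T


def _mean_response(spec: ModelSpec, params: dict[str, float], F: np.ndarray,
                   col: float = 0.0, first: float = 0.0) -> np.ndarray:
    eta = linear_predictor(
        spec, params, F, np.full_like(F, col), np.full_like(F, first)
    )
    if spec.family == "ri":
        return eta
    if spec.family == "death":
        return np.exp(-eta)  # mean years survived s/(1-s)
    if spec.family == "afr":
        return 4.0 + np.exp(eta)
    return 1.0 + np.exp(eta)


def _coef_draws(fit: DCFit, n: int, rng: np.random.Generator) -> list[dict[str, float]]:
    cov = _nearest_psd(fit.cov_mle)
    sims = rng.multivariate_normal(fit.mle, cov, size=n)
    return [dict(zip(fit.param_names, s)) for s in sims]


def confidence_band(
    fit: DCFit,
    grid: np.ndarray | None = None,
    draws: int = 10000,
    seed: int = 0,
    level: float = 0.95,
    col: float = 0.0,
    first: float = 0.0,
) -> dict[str, np.ndarray]:
    """Pointwise band for the fitted mean response over a grid of F values.

    Samples coefficient vectors from MVN(mle, cov_mle) and returns the
    2.5/97.5% quantiles (for level 0.95) of the mean response at each grid F.
    """
    if not fit.converged:
        raise NotConvergedError("bands require a converged fit")
    grid = default_grid() if grid is None else np.asarray(grid)
    rng = np.random.default_rng(seed)
    sims = _coef_draws(fit, draws, rng)
    vals = np.stack([_mean_response(fit.spec, p, grid, col, first) for p in sims])
    alpha = (1 - level) / 2
    lo, hi = np.quantile(vals, [alpha, 1 - alpha], axis=0)
    fitted = _mean_response(fit.spec, fit.params, grid, col, first)
    return {"F": grid, "fit": fitted, "lower": lo, "upper": hi}


def prediction_band(
    fit: DCFit,
    grid: np.ndarray | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    level: float = 0.95,
    col: float = 0.0,
    first: float = 0.0,
) -> dict[str, np.ndarray]:
    """Pointwise band for new responses simulated from the fitted family.

    A single stream of coefficient draws from MVN(mle, cov_mle) -- sized like
    the single 10,000-iteration chain (thin 5, burn-in 5000) used for these
    bands -- generates one response per draw at each grid F; quantiles of the
    simulated responses form the band.
    """
    if not fit.converged:
        raise NotConvergedError("bands require a converged fit")
    grid = default_grid() if grid is None else np.asarray(grid)
    mcmc = mcmc or MCMCConfig(chains=1, iterations=10000, burn_in=5000, thin=5)
    n_draws = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
    rng = np.random.default_rng(seed)
    sims = _coef_draws(fit, n_draws, rng)
    G = len(grid)
    out = np.empty((n_draws, G))
    for s, p in enumerate(sims):
        eta = linear_predictor(
            fit.spec, p, grid, np.full(G, col), np.full(G, first)
        )
        if fit.spec.family == "ri":
            sigma = max(p.get("sigma_r", 1e-6), 1e-9)
            a = (0.0 - eta) / sigma
            y = stats.truncnorm.rvs(a, np.inf, loc=eta, scale=sigma, random_state=rng)
            out[s] = np.minimum(y, MAX_RI_19)
        elif fit.spec.family == "death":
            s_prob = survival_from_eta(eta)
            y = rng.geometric(np.clip(1.0 - s_prob, 1e-12, 1.0)) - 1
            out[s] = np.minimum(y, 19)
        elif fit.spec.family == "afr":
            pr = afr_p_from_eta(eta)
            out[s] = 4 + rng.negative_binomial(4, np.clip(pr, 1e-12, 1.0))
        else:
            pi = wait_pi_from_eta(eta)
            out[s] = 1 + rng.geometric(np.clip(pi, 1e-12, 1.0)) - 1
    alpha = (1 - level) / 2
    lo, hi = np.quantile(out, [alpha, 1 - alpha], axis=0)
    return {"F": grid, "lower": lo, "upper": hi}
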