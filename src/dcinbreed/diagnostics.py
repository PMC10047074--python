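"""MCMC and data-cloning convergence diagnostics."""

from __future__ import annotations

import numpy as np


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor (R-hat) per parameter.

    ``chains`` has shape (n_chains, n_draws) or (n_chains, n_draws, n_params);
    returns a scalar array or per-parameter vector. Classic between/within
    variance form with the sampling-variability correction.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
        squeeze = True
    else:
        squeeze = False
    m, n = chains.shape[0], chains.shape[1]
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if n < 10:
        raise ValueError("R-hat needs at least 10 draws per chain")
    means = chains.mean(axis=1)  # (m, p)
    variances = chains.var(axis=1, ddof=1)  # (m, p)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(W == 0, 1.0, rhat)
    return float(rhat[0]) if squeeze else rhat


def normal_fit_statistics(draws: np.ndarray) -> tuple[float, float]:
    """(ms_error, r_squared) of the multivariate-normal approximation.

    Squared Mahalanobis distances of the pooled draws are compared with their
    chi-squared reference quantiles on a Q-Q basis: ms_error is the mean
    squared deviation of empirical from theoretical quantiles (scaled by the
    dimension), r_squared the squared correlation of the two quantile sets.
    Small ms_error and r_squared near 1 mean the posterior is close to
    multivariate normal, which data cloning requires at the final clone level.
    """
    from scipy import stats

    draws = np.atleast_2d(draws)
    if draws.shape[1] == 1 or draws.ndim == 1:
        draws = draws.reshape(-1, 1)
    n, p = draws.shape
    mean = draws.mean(axis=0)
    cov = np.cov(draws.T).reshape(p, p)
    # ridge for numerically singular covariances
    cov = cov + 1e-12 * np.eye(p)
    delta = draws - mean
    d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
    d2.sort()
    probs = (np.arange(1, n + 1) - 0.5) / n
    ref = stats.chi2.ppf(probs, df=p)
    ms_error = float(np.mean((d2 - ref) ** 2) / p)
    r = np.corrcoef(d2, ref)[0, 1]
    return ms_error, float(r**2)
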