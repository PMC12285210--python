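"""Poisson log normal (PLN) abundance model.

Each species carries a latent sampling rate Lambda = exp(Z) with
Z ~ Normal(mu, sigma), and its observed count is Poisson(Lambda).  The
marginal PMF is

    P(x) = integral Poisson(x; e^z) Normal(z; mu, sigma) dz,

evaluated by Gauss-Hermite quadrature after recentring the integrand at
the mode of its log (the integrand becomes extremely peaked for large x,
and naive quadrature centred at mu underflows).  The zero class P(0) is
the probability that a pool species goes unobserved, so a zero-truncated
maximum-likelihood fit of (mu, sigma) implies total community richness
R = S / (1 - P(0)).

sigma = 0 degenerates to a plain Poisson(e^mu); it is accepted by the
PMF and the sampler but not by the fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from ._util import as_rng, validate_counts
from .cegs import ModelFit

__all__ = ["PLNParams", "pln_pmf", "pln_sample", "pln_fit"]

logger = logging.getLogger(__name__)

DEFAULT_N_QUAD = 200


@dataclass
class PLNParams:
    """Location ``mu`` and spread ``sigma`` (both nats) of the log rate."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        self.mu = float(self.mu)
        self.sigma = float(self.sigma)
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (self.sigma >= 0.0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")


def _log_pmf(x: np.ndarray, mu: float, sigma: float, n_quad: int,
             _chunk: int = 20000) -> np.ndarray:
    # bound the (n_x, n_quad) work arrays to ~tens of MB
    if len(x) > _chunk:
        return np.concatenate([
            _log_pmf(x[i:i + _chunk], mu, sigma, n_quad)
            for i in range(0, len(x), _chunk)
        ])
    return _log_pmf_block(x, mu, sigma, n_quad)


def _log_pmf_block(x: np.ndarray, mu: float, sigma: float, n_quad: int) -> np.ndarray:
    """Vectorised log P(x) by mode-recentred Gauss-Hermite quadrature.

    For each count the log-integrand h(z) = x z - e^z - lgamma(x+1)
    + log phi(z; mu, sigma) is strictly concave; Newton's method finds
    its mode z*, and the quadrature is taken in the local scale
    1/sqrt(-h''(z*)).  Accumulation is log-sum-exp throughout.
    """
    x = x.astype(float)
    var = sigma * sigma
    # Newton for the mode: h'(z) = x - e^z - (z - mu)/var, h'' = -e^z - 1/var
    z = np.where(x > 0, np.log(np.maximum(x, 1e-12)), mu)
    z = np.minimum(z, mu + 40.0 * max(sigma, 1.0))
    for _ in range(80):
        ez = np.exp(z)
        grad = x - ez - (z - mu) / var
        hess = -ez - 1.0 / var
        step = grad / hess
        z_new = z - step
        z = z_new
        if np.max(np.abs(step)) < 1e-12:
            break
    s = 1.0 / np.sqrt(np.exp(z) + 1.0 / var)  # local curvature scale

    t, w = hermgauss(n_quad)
    keep = w > 0
    t, log_w = t[keep], np.log(w[keep])
    # nodes z_ij = z*_i + sqrt(2) s_i t_j ; integral = sqrt(2) s_i * sum_j
    #   w_j e^{t_j^2} f(z_ij)   with f = exp(h)
    zz = z[:, None] + math.sqrt(2.0) * s[:, None] * t[None, :]
    h = (
        x[:, None] * zz
        - np.exp(np.minimum(zz, 700.0))  # overflow guard: such nodes carry no mass
        - gammaln(x + 1.0)[:, None]
        - 0.5 * ((zz - mu) ** 2) / var
        - 0.5 * math.log(2.0 * math.pi * var)
    )
    return (
        0.5 * math.log(2.0)
        + np.log(s)
        + logsumexp(h + (t * t)[None, :] + log_w[None, :], axis=1)
    )


def pln_pmf(x, params: PLNParams, n_quad: int = DEFAULT_N_QUAD) -> np.ndarray | float:
    """Marginal PMF P(x) for x in {0, 1, 2, ...}."""
    if n_quad < 40:
        raise ValueError("n_quad must be >= 40")
    xa = np.asarray(x)
    xi = np.floor(xa).astype(np.int64)
    if np.any(xa != xi) or np.any(xi < 0):
        raise ValueError("x must be non-negative integers")
    if params.sigma == 0.0:
        out = poisson.pmf(xi, math.exp(params.mu))
        return float(out) if xa.ndim == 0 else out
    out = np.exp(_log_pmf(np.atleast_1d(xi), params.mu, params.sigma, n_quad))
    return float(out[0]) if xa.ndim == 0 else out.reshape(xa.shape)


def pln_sample(pool_size: int, params: PLNParams,
               seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Draw one community: ``pool_size`` Poisson counts with log normal rates."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = as_rng(seed)
    rates = np.exp(rng.normal(params.mu, params.sigma, size=pool_size))
    return rng.poisson(rates)


def _pln_nll(theta: np.ndarray, vals: np.ndarray, mult: np.ndarray, n_quad: int) -> float:
    """Negative zero-truncated log-likelihood at theta = (mu, ln sigma)."""
    mu, sigma = theta[0], math.exp(theta[1])
    with_zero = np.concatenate(([0], vals))
    log_p = _log_pmf(with_zero, mu, sigma, n_quad)
    p0 = math.exp(min(log_p[0], 0.0))
    log_obs = math.log1p(-min(p0, 1 - 1e-15))
    ll = float((mult * (log_p[1:] - log_obs)).sum())
    return -ll if math.isfinite(ll) else 1e12


def pln_fit(inv, n_quad: int = DEFAULT_N_QUAD) -> ModelFit:
    """Zero-truncated maximum-likelihood PLN fit on raw counts.

    Requires at least 3 species and 2 distinct count values (two free
    parameters).  Optimisation runs quasi-Newton in (mu, ln sigma) from
    three deterministic starts — the method of moments on log counts and
    +/-1 shifts of mu — with the best likelihood winning and ties broken
    by smaller sigma.
    """
    counts = validate_counts(getattr(inv, "counts", inv))
    S_obs = int(len(counts))
    if S_obs < 3:
        raise ValueError(f"PLN fit requires at least 3 species, got {S_obs}")
    vals, mult = np.unique(counts, return_counts=True)
    if len(vals) < 2:
        raise ValueError("PLN fit requires at least 2 distinct count values")
    mult = mult.astype(float)

    log_c = np.log(np.sort(counts).astype(float))  # sorted: order-invariant sums
    mu0 = float(log_c.mean())
    sigma0 = max(float(log_c.std(ddof=1)), 0.1)
    starts = [(mu0, math.log(sigma0)), (mu0 - 1.0, math.log(sigma0)), (mu0 + 1.0, math.log(sigma0))]
    bounds = [(-50.0, 50.0), (math.log(1e-3), math.log(50.0))]

    best = None
    n_eval = 0
    any_converged = False
    for x0 in starts:
        res = minimize(_pln_nll, np.asarray(x0), args=(vals, mult, n_quad),
                       method="L-BFGS-B", bounds=bounds)
        n_eval += int(res.nfev)
        any_converged = any_converged or bool(res.success)
        cand = (res.fun, res.x[0], math.exp(res.x[1]), bool(res.success))
        if best is None or cand[0] < best[0] - 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9 and cand[2] < best[2]
        ):
            best = cand
    nll, mu_hat, sigma_hat, _ = best
    if not any_converged:
        logger.warning("PLN fit: no optimiser start reported convergence")
    params = PLNParams(mu_hat, sigma_hat)
    p0 = float(pln_pmf(0, params, n_quad=n_quad))
    return ModelFit(
        model="pln",
        params=params,
        loglik=-nll,
        p0=p0,
        S_obs=S_obs,
        R_hat=S_obs / (1.0 - p0),
        converged=any_converged,
        n_eval=n_eval,
    )
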