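"""Compound exponential-geometric series (CEGS) abundance model.

The model compounds a geometric count distribution over a latent
per-species abundance.  Each species draws E ~ Exponential(1) (the
negative log of a uniform variate) and gets the latent abundance
w = E**gamma / lam, a Weibull-type variate: gamma is a shape parameter
governing variation in counts and lam an inverse scale governing their
magnitude.  The observed count is geometric on {0, 1, 2, ...}:

    P(x | E) = (1 - p(E))**x * p(E)

Two readings of the per-species geometric parameter are supported, both
with p(E) as written, p(E) = 1/(w + 1):

* ``convention="stopping"`` (default): p(E) is the geometric stopping
  probability, so the species' expected count is (1-p)/p = w.
* ``convention="continuation"``: p(E) is the continuation probability,
  i.e. the stopping probability is 1 - p(E) = w/(w + 1) and the expected
  count is 1/w.

The marginal PMF is the expectation over E (Gauss-Laguerre quadrature),
its zero class p0 = E[P(0 | E)] is the probability a pool species is
unobserved, and richness extrapolates from the observed count S as
R = S / (1 - p0).  Fitting maximises the zero-truncated likelihood on
counts that have been "compressed" (the two largest replaced by the
second-smallest distinct value) to damp the influence of outliers.

With gamma = 0 the latent abundance is constant and the model collapses
to a pure geometric with stopping probability lam/(1 + lam).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh_tridiagonal
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from ._util import as_rng, validate_counts

__all__ = [
    "CEGSParams",
    "ModelFit",
    "CONVENTIONS",
    "cegs_stop_prob",
    "cegs_p0",
    "cegs_pmf",
    "cegs_survival",
    "compress_counts",
    "cegs_fit",
    "cegs_sample",
]

logger = logging.getLogger(__name__)

CONVENTIONS = ("stopping", "continuation")
DEFAULT_N_QUAD = 120

# optimiser search box for (gamma, lam)
_GAMMA_BOUNDS = (1e-3, 50.0)
_LAM_BOUNDS = (1e-6, 1e6)


@dataclass
class CEGSParams:
    """CEGS parameters: shape ``gamma`` >= 0 and inverse scale ``lam`` > 0."""

    gamma: float
    lam: float

    def __post_init__(self) -> None:
        self.gamma = float(self.gamma)
        self.lam = float(self.lam)
        if not (self.gamma >= 0.0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be finite and >= 0, got {self.gamma}")
        if not (self.lam > 0.0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be finite and > 0, got {self.lam}")


@dataclass
class ModelFit:
    """Result of a zero-truncated maximum-likelihood fit (CEGS or PLN).

    ``R_hat = S_obs / (1 - p0)`` extrapolates total pool richness from
    the fitted zero-class probability; it is reported unrounded.
    """

    model: str
    params: object
    loglik: float
    p0: float
    S_obs: int
    R_hat: float
    converged: bool
    n_eval: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 < 1.0:
            raise ValueError(f"p0 must lie in [0, 1), got {self.p0}")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": vars(self.params),
            "loglik": self.loglik,
            "p0": self.p0,
            "S_obs": self.S_obs,
            "R_hat": self.R_hat,
            "converged": self.converged,
            "n_eval": self.n_eval,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}, got {convention!r}")


def _log_w(E: np.ndarray, params: CEGSParams) -> np.ndarray:
    """log of the latent abundance w = E**gamma / lam."""
    return params.gamma * np.log(E) - math.log(params.lam)


def _log_stop(E: np.ndarray, params: CEGSParams, convention: str) -> tuple[np.ndarray, np.ndarray]:
    """(log stopping prob, log continuation prob) per latent variate E."""
    lw = _log_w(E, params)
    # log(1/(w+1)) = -log1p(w) computed stably from log w
    log_inv = -np.logaddexp(0.0, lw)       # log 1/(w+1)
    log_comp = lw + log_inv                # log w/(w+1)
    if convention == "stopping":
        return log_inv, log_comp
    return log_comp, log_inv


def cegs_stop_prob(E, params: CEGSParams, convention: str = "stopping") -> np.ndarray | float:
    """Per-species geometric stopping probability at latent variate ``E`` > 0."""
    _check_convention(convention)
    arr = np.asarray(E, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("E must be > 0")
    log_stop, _ = _log_stop(arr, params, convention)
    out = np.exp(log_stop)
    return float(out) if np.isscalar(E) or arr.ndim == 0 else out


_NODE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _quad_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    if n_quad < 40:
        raise ValueError("n_quad must be >= 40")
    if n_quad not in _NODE_CACHE:
        # Golub-Welsch on the Laguerre Jacobi matrix: stable at high order,
        # where the recurrence-based node generators overflow
        diag = 2.0 * np.arange(n_quad) + 1.0
        off = np.arange(1.0, n_quad)
        x, v = eigh_tridiagonal(diag, off)
        w = v[0] ** 2  # total weight integral e^-E dE = 1
        keep = w > 0  # drop weights that underflow at the far tail
        _NODE_CACHE[n_quad] = (x[keep], np.log(w[keep]))
    return _NODE_CACHE[n_quad]


def cegs_p0(params: CEGSParams, n_quad: int = DEFAULT_N_QUAD,
            convention: str = "stopping") -> float:
    """Zero-class probability p0 = E[P(0 | E)], E ~ Exponential(1).

    Evaluated by Gauss-Laguerre quadrature; equals ``cegs_pmf(0, ...)``.
    """
    return float(cegs_pmf(0, params, n_quad=n_quad, convention=convention))


def cegs_pmf(x, params: CEGSParams, n_quad: int = DEFAULT_N_QUAD,
             convention: str = "stopping") -> np.ndarray | float:
    """Marginal PMF P(x) = E[(1-p(E))**x p(E)] on x in {0, 1, 2, ...}."""
    _check_convention(convention)
    xa = np.asarray(x)
    xi = np.floor(xa).astype(np.int64)
    if np.any(xa != xi) or np.any(xi < 0):
        raise ValueError("x must be non-negative integers")
    nodes, log_w = _quad_nodes(n_quad)
    log_stop, log_cont = _log_stop(nodes, params, convention)
    # log integrand per (x, node); logsumexp over nodes, chunked for memory
    flat = xi.reshape(-1)
    parts = []
    for i in range(0, flat.size, 50000):
        terms = flat[i:i + 50000, None] * log_cont + log_stop + log_w
        parts.append(np.exp(logsumexp(terms, axis=-1)))
    out = np.concatenate(parts).reshape(xi.shape)
    return float(out) if xa.ndim == 0 else out


def cegs_survival(x, params: CEGSParams, n_quad: int = DEFAULT_N_QUAD,
                  convention: str = "stopping") -> np.ndarray | float:
    """P(X > x) = E[(1-p(E))**(x+1)]; the truncation correction for PMF sums."""
    _check_convention(convention)
    xa = np.asarray(x)
    xi = np.floor(xa).astype(np.int64)
    if np.any(xa != xi) or np.any(xi < 0):
        raise ValueError("x must be non-negative integers")
    nodes, log_w = _quad_nodes(n_quad)
    _, log_cont = _log_stop(nodes, params, convention)
    flat = xi.reshape(-1)
    parts = []
    for i in range(0, flat.size, 50000):
        terms = (flat[i:i + 50000, None] + 1) * log_cont + log_w
        parts.append(np.exp(logsumexp(terms, axis=-1)))
    out = np.concatenate(parts).reshape(xi.shape)
    return float(out) if xa.ndim == 0 else out


def compress_counts(counts) -> np.ndarray:
    """Damp outliers by replacing the two largest counts with the
    second-smallest distinct count value.

    The multiset is sorted ascending and the last two positions are
    replaced regardless of ties; output is returned sorted ascending and
    has the same length (species count is unchanged).  Requires at least
    five species and at least three distinct count values.
    """
    c = np.sort(validate_counts(counts))
    if len(c) < 5:
        raise ValueError(
            f"count compression requires at least 5 species, got {len(c)}"
        )
    distinct = np.unique(c)
    if len(distinct) < 3:
        raise ValueError(
            f"count compression requires at least 3 distinct count values, got {len(distinct)}"
        )
    out = c.copy()
    out[-2:] = distinct[1]
    return np.sort(out)


def _unique_weights(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, mult = np.unique(counts, return_counts=True)
    return vals, mult.astype(float)


def _cegs_nll(theta: np.ndarray, vals: np.ndarray, mult: np.ndarray,
              nodes: np.ndarray, log_w: np.ndarray, convention: str) -> float:
    """Negative zero-truncated log-likelihood at theta = (ln gamma, ln lam)."""
    params = CEGSParams(math.exp(theta[0]), math.exp(theta[1]))
    log_stop, log_cont = _log_stop(nodes, params, convention)
    terms = vals[:, None] * log_cont + log_stop + log_w
    log_px = logsumexp(terms, axis=1)
    log_p0 = logsumexp(log_stop + log_w)
    log_obs = math.log1p(-min(math.exp(log_p0), 1 - 1e-15))
    ll = float((mult * (log_px - log_obs)).sum())
    return -ll if math.isfinite(ll) else 1e12


def cegs_fit(inv, n_quad: int = DEFAULT_N_QUAD, convention: str = "stopping",
             compress: bool = True) -> ModelFit:
    """Zero-truncated maximum-likelihood CEGS fit.

    Counts are compressed before entering the likelihood (pass
    ``compress=False`` only for debugging: raw-count fits are noticeably
    less precise).  The observed richness S is taken from the raw counts
    — compression never changes S — and R_hat = S/(1 - p0) at the
    optimum.  Optimisation runs quasi-Newton in (ln gamma, ln lam) from
    four deterministic starts; the best likelihood wins, ties broken by
    smaller gamma.
    """
    _check_convention(convention)
    raw = validate_counts(getattr(inv, "counts", inv))
    S_obs = int(len(raw))
    work = compress_counts(raw) if compress else np.sort(raw)
    vals, mult = _unique_weights(work)
    if len(vals) < 2:
        raise ValueError("CEGS fit needs at least 2 distinct count values")
    nodes, log_w = _quad_nodes(n_quad)

    mean_c = float(work.mean())
    starts = []
    for g0 in (0.5, 2.0):
        # moment-matched lam under the stopping convention:
        # E[count] = E[E**gamma]/lam = Gamma(gamma + 1)/lam
        lam_mm = math.exp(gammaln(g0 + 1.0)) / mean_c
        for l0 in (lam_mm, 1.0):
            starts.append((math.log(g0), math.log(max(min(l0, _LAM_BOUNDS[1]), _LAM_BOUNDS[0]))))

    bounds = [
        (math.log(_GAMMA_BOUNDS[0]), math.log(_GAMMA_BOUNDS[1])),
        (math.log(_LAM_BOUNDS[0]), math.log(_LAM_BOUNDS[1])),
    ]
    best = None
    n_eval = 0
    any_converged = False
    for x0 in starts:
        res = minimize(
            _cegs_nll, np.asarray(x0),
            args=(vals, mult, nodes, log_w, convention),
            method="L-BFGS-B", bounds=bounds,
        )
        n_eval += int(res.nfev)
        any_converged = any_converged or bool(res.success)
        cand = (res.fun, math.exp(res.x[0]), math.exp(res.x[1]), bool(res.success))
        if best is None or cand[0] < best[0] - 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]
        ):
            best = cand
    nll, gamma_hat, lam_hat, _ = best
    if not any_converged:
        logger.warning("CEGS fit: no optimiser start reported convergence")
    params = CEGSParams(gamma_hat, lam_hat)
    p0 = cegs_p0(params, n_quad=n_quad, convention=convention)
    return ModelFit(
        model="cegs",
        params=params,
        loglik=-nll,
        p0=p0,
        S_obs=S_obs,
        R_hat=S_obs / (1.0 - p0),
        converged=any_converged,
        n_eval=n_eval,
    )


def cegs_sample(pool_size: int, params: CEGSParams,
                seed: int | np.random.Generator | None = None,
                convention: str = "stopping") -> np.ndarray:
    """Draw one community: ``pool_size`` counts (zeros included).

    Per species: E = -ln(U) with U ~ Uniform(0,1), then a geometric count
    on {0, 1, 2, ...} with the stopping probability implied by E under
    the chosen convention.
    """
    _check_convention(convention)
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = as_rng(seed)
    E = -np.log(rng.uniform(size=pool_size))
    log_stop, _ = _log_stop(E, params, convention)
    p = np.exp(log_stop)
    # numpy's geometric counts trials to first success on {1, 2, ...}
    return rng.geometric(np.clip(p, 1e-300, 1.0)) - 1
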