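"""Classical diversity and evenness statistics.

All entropies are in nats and all Hill numbers are in "species
equivalents": the number of equally-abundant species that would produce
the same index value.  For a count vector with proportions p_i:

* richness            S            (Hill number of order 0)
* Shannon entropy     H = -sum p_i ln p_i,  e^H  (Hill order 1)
* Simpson concentration D = sum p_i^2,  1/D    (Hill order 2)
* Pielou evenness     J = H / ln S
* Berger-Parker dominance d = max p_i          (1/d is Hill order +inf)
* logged Hill ratio   H + ln D = ln(e^H / (1/D)) >= 0, zero iff all
  counts are equal
* Fisher's log-series alpha, solving S = alpha ln(1 + N/alpha), with the
  log-series scale x = N/(N + alpha)

Statistics that are undefined for an input (J when S < 2, alpha when
S >= N) are reported as NaN — an explicit missing marker, never a zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from ._util import validate_counts

__all__ = [
    "DiversityProfile",
    "shannon_H",
    "simpson_D",
    "pielou_J",
    "berger_parker_d",
    "hill_number",
    "hill_ratio",
    "fishers_alpha",
    "diversity_profile",
]

PROFILE_FIELDS = (
    "S", "N", "H", "expH", "D", "invD", "J", "d", "hill_ratio", "alpha", "x_ls",
)


def _proportions(counts) -> np.ndarray:
    c = validate_counts(counts)
    return c / c.sum()


def shannon_H(counts) -> float:
    """Shannon entropy H = -sum p ln p in nats; 0 for a single species."""
    p = _proportions(counts)
    return float(-(p * np.log(p)).sum())


def simpson_D(counts) -> float:
    """Plug-in Simpson concentration D = sum p^2 (no small-sample correction)."""
    p = _proportions(counts)
    return float((p * p).sum())


def pielou_J(counts) -> float:
    """Pielou's evenness J = H / ln S; requires S >= 2."""
    c = validate_counts(counts)
    if len(c) < 2:
        raise ValueError("Pielou's J requires at least two species (ln S > 0)")
    return shannon_H(c) / math.log(len(c))


def berger_parker_d(counts) -> float:
    """Berger-Parker dominance: proportional abundance of the most common species."""
    c = validate_counts(counts)
    return float(c.max() / c.sum())


def hill_number(counts, q: float) -> float:
    """Hill number of order ``q`` in species equivalents.

    q=0 gives richness, q=1 exp(H), q=2 1/D, q=+inf the reciprocal of the
    Berger-Parker dominance and q=-inf the reciprocal of the rarest
    species' proportion.  Negative finite orders are computed by the same
    formula and are dominated by rare species.
    """
    p = _proportions(counts)
    if math.isinf(q):
        return float(1.0 / p.max()) if q > 0 else float(1.0 / p.min())
    if abs(q - 1.0) < 1e-12:
        return float(math.exp(-(p * np.log(p)).sum()))
    if q == 0:
        return float(len(p))
    # (sum p^q)^(1/(1-q)) via log-sum-exp for numerical range
    return float(math.exp(logsumexp(q * np.log(p)) / (1.0 - q)))


def hill_ratio(counts) -> float:
    """Logged Hill ratio H + ln D = ln(e^H D); >= 0, zero iff counts are equal."""
    p = _proportions(counts)
    H = float(-(p * np.log(p)).sum())
    D = float((p * p).sum())
    return H + math.log(D)


def fishers_alpha(S: int, N: int) -> tuple[float, float]:
    """Fisher's log-series alpha and scale x for S observed species, N individuals.

    Solves S = alpha ln(1 + N/alpha) by bracketed root finding (relative
    tolerance 1e-10).  alpha diverges as S -> N, so N > S >= 1 is required;
    returns ``(alpha, x)`` with x = N/(N + alpha) in (0, 1).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if S >= N:
        raise ValueError(f"Fisher's alpha needs N > S (got S={S}, N={N})")

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    # a*ln(1+N/a) increases from 0 (a->0+) to N (a->inf), so a root exists
    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 4.0
        if hi > 1e15:  # pragma: no cover - unreachable for valid S < N
            raise RuntimeError("failed to bracket Fisher's alpha")
    alpha = brentq(f, lo, hi, rtol=1e-10, maxiter=200)
    return float(alpha), float(N / (N + alpha))


@dataclass
class DiversityProfile:
    """All index values for one inventory; NaN marks undefined statistics."""

    S: int
    N: int
    H: float
    expH: float
    D: float
    invD: float
    J: float
    d: float
    hill_ratio: float
    alpha: float
    x_ls: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in PROFILE_FIELDS}


def diversity_profile(inv) -> DiversityProfile:
    """Compute the full :class:`DiversityProfile` for an inventory or count vector."""
    counts = validate_counts(getattr(inv, "counts", inv))
    S, N = int(len(counts)), int(counts.sum())
    H = shannon_H(counts)
    D = simpson_D(counts)
    J = pielou_J(counts) if S >= 2 else math.nan
    if N > S:
        alpha, x_ls = fishers_alpha(S, N)
    else:
        alpha, x_ls = math.nan, math.nan
    return DiversityProfile(
        S=S,
        N=N,
        H=H,
        expH=math.exp(H),
        D=D,
        invD=1.0 / D,
        J=J,
        d=berger_parker_d(counts),
        hill_ratio=H + math.log(D),
        alpha=alpha,
        x_ls=x_ls,
    )
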