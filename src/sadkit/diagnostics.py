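"""Robustness diagnostics for diversity statistics.

Five procedures probe how stable an index is under manipulations that
should leave a trustworthy statistic (approximately) unchanged:

* dominant removal — drop the single most common species and recompute;
* bootstrap — resample the S counts with replacement (S is fixed and the
  expected total stays put, so a robust index should not drift);
* reciprocal-sum pair matching — pair each inventory with the one whose
  counts have the most similar sum of reciprocals (a rare-species
  fingerprint that largely ignores dominants) and correlate the pairs;
* paired summaries — Spearman rank correlation plus the fraction of
  manipulated values falling above the line of unity;
* latitudinal summaries — per-site metric values against latitude with a
  local-regression smooth and the SD of logged values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from ._util import as_rng, validate_counts
from .indices import diversity_profile
from .inventories import Inventory

__all__ = [
    "PairSet",
    "LatitudinalSummary",
    "remove_dominant",
    "bootstrap_inventory",
    "reciprocal_sum",
    "match_pairs",
    "paired_metric_summary",
    "latitudinal_summary",
]

logger = logging.getLogger(__name__)


def remove_dominant(inv: Inventory) -> Inventory:
    """Drop exactly one species with the maximal count (first in stored order)."""
    counts = inv.counts
    if len(counts) < 2:
        raise ValueError("removing the dominant requires at least 2 species")
    k = int(np.argmax(counts))
    keep = np.ones(len(counts), dtype=bool)
    keep[k] = False
    species = [s for s, m in zip(inv.species, keep) if m] if inv.species else None
    return Inventory(
        site_id=inv.site_id,
        counts=counts[keep],
        species=species,
        taxon_group=inv.taxon_group,
        latitude=inv.latitude,
    )


def bootstrap_inventory(inv: Inventory, seed: int | np.random.Generator | None = None) -> Inventory:
    """Resample the S counts fully, with replacement; S is fixed by design."""
    rng = as_rng(seed)
    counts = rng.choice(inv.counts, size=len(inv.counts), replace=True)
    return Inventory(
        site_id=inv.site_id,
        counts=counts,
        taxon_group=inv.taxon_group,
        latitude=inv.latitude,
    )


def reciprocal_sum(counts) -> float:
    """Sum of reciprocal counts: similar values mean similar rare-species content."""
    c = validate_counts(counts)
    return float((1.0 / c).sum())


@dataclass
class PairSet:
    """Nearest-neighbour pairing of inventories by reciprocal sum."""

    pairs: list[tuple[int, int]]
    r_values: np.ndarray


def match_pairs(inventories) -> PairSet:
    """Pair each inventory with the distinct one of most similar reciprocal sum.

    Nearest neighbour with reuse allowed; ties broken by the lower index.
    """
    invs = list(inventories)
    if len(invs) < 2:
        raise ValueError("pair matching requires at least 2 inventories")
    r = np.array([reciprocal_sum(getattr(inv, "counts", inv)) for inv in invs])
    pairs = []
    for i in range(len(invs)):
        d = np.abs(r - r[i])
        d[i] = np.inf
        pairs.append((i, int(np.argmin(d))))  # argmin takes the lowest index on ties
    return PairSet(pairs=pairs, r_values=r)


def paired_metric_summary(original, manipulated) -> tuple[float, float]:
    """Spearman rho and the fraction of manipulated values above the originals.

    Ranks use the average-rank convention.  Exact ties with the original
    are excluded from both numerator and denominator of the fraction; if
    every pair is tied, the fraction is NaN.
    """
    x = np.asarray(original, dtype=float)
    y = np.asarray(manipulated, dtype=float)
    if x.shape != y.shape:
        raise ValueError("original and manipulated must have equal length")
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if len(x) < 3:
        raise ValueError("paired summary requires at least 3 finite pairs")
    if np.array_equal(x, y):
        rho = 1.0
    else:
        rho = float(spearmanr(x, y).statistic)
    non_tied = x != y
    frac = float((y[non_tied] > x[non_tied]).mean()) if non_tied.any() else math.nan
    return rho, frac


@dataclass
class LatitudinalSummary:
    """Per-site metric values along latitude plus a descriptive smooth."""

    latitudes: np.ndarray
    values: np.ndarray
    grid: np.ndarray
    smooth: np.ndarray
    sd_of_logs: float


def _loess(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
           span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights (descriptive only)."""
    n = len(x)
    q = max(int(math.ceil(span * n)), degree + 1)
    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        if h == 0:
            out[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        use = w > 0
        dx = x[use] - x0
        design = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[use] * sw, rcond=None)
        out[i] = beta[0]
    return out


def latitudinal_summary(inventories, metric: str = "expH", span: float = 0.75,
                        n_grid: int = 100) -> LatitudinalSummary:
    """Metric values vs. latitude, their log-scale SD, and a loess smooth.

    ``metric`` names any :class:`~sadkit.indices.DiversityProfile` field.
    Inventories without a latitude or with a nonpositive / missing metric
    value are excluded (with a logged warning); at least 5 usable sites
    are required.  The smooth is a span-0.75 local quadratic regression of
    the logged metric on latitude and carries no inferential weight.
    """
    lats, vals = [], []
    n_dropped = 0
    for inv in inventories:
        if inv.latitude is None:
            n_dropped += 1
            continue
        v = getattr(diversity_profile(inv), metric)
        if not (np.isfinite(v) and v > 0):
            n_dropped += 1
            continue
        lats.append(inv.latitude)
        vals.append(float(v))
    if n_dropped:
        logger.warning(
            "latitudinal_summary: excluded %d inventories (no latitude or "
            "nonpositive %s)", n_dropped, metric,
        )
    if len(vals) < 5:
        raise ValueError(f"latitudinal summary requires >= 5 usable sites, got {len(vals)}")
    lats = np.asarray(lats)
    vals = np.asarray(vals)
    log_v = np.log(vals)
    sd = float(log_v.std(ddof=1))
    grid = np.linspace(lats.min(), lats.max(), n_grid)
    smooth = _loess(lats, log_v, grid, span=span, degree=2)
    return LatitudinalSummary(
        latitudes=lats, values=vals, grid=grid, smooth=smooth, sd_of_logs=sd
    )
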