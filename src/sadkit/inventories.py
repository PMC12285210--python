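"""Count inventories: the data model, long-format I/O, and synthetic fixtures.

An inventory is one site's census: a multiset of positive integer counts,
one per observed species, optionally tagged with a taxon group and a
latitude.  The canonical file format is a long table with one row per
(site, species) pair and columns ``site``, ``species``, ``count`` plus
optional ``latitude`` and ``group``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng, validate_counts

__all__ = [
    "Inventory",
    "InventoryFormatError",
    "read_inventories",
    "write_inventories",
    "generate_fixture",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site", "species", "count")
_DIALECT_SEP = {"long-csv": ",", "long-tsv": "\t"}


class InventoryFormatError(ValueError):
    """Raised when an input table is structurally unusable."""


@dataclass
class Inventory:
    """One site's species counts.

    Every count is an integer >= 1.  ``species`` labels are optional
    bookkeeping: no statistic in this package uses them.
    """

    site_id: str
    counts: np.ndarray
    species: list[str] | None = None
    taxon_group: str | None = None
    latitude: float | None = None

    def __post_init__(self) -> None:
        self.counts = validate_counts(self.counts)
        if self.species is not None and len(self.species) != len(self.counts):
            raise ValueError(
                f"site {self.site_id!r}: {len(self.species)} species labels "
                f"for {len(self.counts)} counts"
            )
        if self.latitude is not None:
            self.latitude = float(self.latitude)
            if not -90.0 <= self.latitude <= 90.0:
                raise ValueError(f"latitude {self.latitude} outside [-90, 90]")

    @property
    def S(self) -> int:
        """Observed species richness (number of counts)."""
        return int(len(self.counts))

    @property
    def N(self) -> int:
        """Total number of individuals (sum of counts)."""
        return int(self.counts.sum())


def read_inventories(path, dialect: str = "long-csv") -> list[Inventory]:
    """Read inventories from a long-format delimited file.

    One :class:`Inventory` is returned per distinct ``site`` value, in
    order of first appearance; species order within a site is preserved
    as read.  Bad rows are never dropped silently: any count that is not
    an integer >= 1 raises, naming the offending row.
    """
    if dialect not in _DIALECT_SEP:
        raise InventoryFormatError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=_DIALECT_SEP[dialect])
    except pd.errors.EmptyDataError as exc:
        raise InventoryFormatError(f"{path}: file is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InventoryFormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise InventoryFormatError(f"{path}: no data rows")

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 1) | (counts != np.floor(counts))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: row {row + 2} has invalid count {df['count'].iloc[row]!r} "
            "(must be an integer >= 1)"
        )

    inventories = []
    for site, grp in df.groupby("site", sort=False):
        lat = None
        if "latitude" in grp.columns:
            lats = grp["latitude"].dropna().unique()
            if len(lats) > 1:
                raise ValueError(f"site {site!r}: conflicting latitudes {lats}")
            if len(lats) == 1:
                lat = float(lats[0])
        group = None
        if "group" in grp.columns:
            groups = grp["group"].dropna().unique()
            if len(groups) >= 1:
                group = str(groups[0])
        inventories.append(
            Inventory(
                site_id=str(site),
                counts=grp["count"].to_numpy(dtype=np.int64),
                species=[str(s) for s in grp["species"]],
                taxon_group=group,
                latitude=lat,
            )
        )
    logger.info("read %d inventories from %s", len(inventories), path)
    return inventories


def write_inventories(inventories, path, dialect: str = "long-csv") -> None:
    """Write inventories as a long table; inverse of :func:`read_inventories`."""
    if dialect not in _DIALECT_SEP:
        raise InventoryFormatError(f"unknown dialect {dialect!r}")
    rows = []
    for inv in inventories:
        labels = inv.species or [f"sp{i + 1}" for i in range(inv.S)]
        for sp, n in zip(labels, inv.counts):
            rows.append(
                {
                    "site": inv.site_id,
                    "species": sp,
                    "count": int(n),
                    "latitude": inv.latitude,
                    "group": inv.taxon_group,
                }
            )
    df = pd.DataFrame(rows, columns=["site", "species", "count", "latitude", "group"])
    if df["latitude"].isna().all():
        df = df.drop(columns=["latitude"])
    if df["group"].isna().all():
        df = df.drop(columns=["group"])
    df.to_csv(path, sep=_DIALECT_SEP[dialect], index=False)


def generate_fixture(
    model: str,
    params,
    pool_size: int,
    n_inventories: int,
    seed: int | np.random.Generator | None,
) -> list[Inventory]:
    """Draw synthetic inventories from one of the two abundance models.

    Each inventory is an independent draw of ``pool_size`` species from
    the named model's sampler; species with count zero are unobserved and
    therefore dropped.  Deterministic for a fixed integer seed.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if n_inventories < 1:
        raise ValueError("n_inventories must be >= 1")
    # local imports: those modules do not import this one
    from .cegs import CEGSParams, cegs_sample
    from .pln import PLNParams, pln_sample

    rng = as_rng(seed)
    inventories = []
    for k in range(n_inventories):
        if model == "pln":
            if not isinstance(params, PLNParams):
                params = PLNParams(*params)
            raw = pln_sample(pool_size, params, seed=rng)
        elif model == "cegs":
            if not isinstance(params, CEGSParams):
                params = CEGSParams(*params)
            raw = cegs_sample(pool_size, params, seed=rng)
        else:
            raise ValueError(f"unknown model {model!r} (expected 'pln' or 'cegs')")
        observed = np.flatnonzero(raw > 0)
        if observed.size == 0:
            logger.warning("fixture draw %d observed zero species; emitting empty site skipped", k)
            continue
        inventories.append(
            Inventory(
                site_id=f"sim{k + 1}",
                counts=raw[observed],
                species=[f"sp{i + 1}" for i in observed],
            )
        )
    return inventories
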