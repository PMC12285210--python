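"""Small shared helpers (validation, RNG policy)."""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "validate_counts"]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a NumPy Generator.

    All stochastic operations in this package take an explicit ``seed``
    (an integer, an existing Generator, or None for OS entropy) and never
    touch NumPy's global RNG state.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def validate_counts(counts, *, allow_empty: bool = False) -> np.ndarray:
    """Coerce a multiset of species counts to an int64 array.

    Counts must be integers >= 1: a species with zero individuals is by
    definition unobserved and has no place in an inventory.
    """
    arr = np.asarray(counts)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.size == 0:
        if allow_empty:
            return arr.astype(np.int64)
        raise ValueError("counts are empty: at least one species is required")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be numeric")
    as_int = np.floor(arr).astype(np.int64)
    if np.any(arr != as_int):
        bad = np.flatnonzero(np.asarray(arr != as_int))[0]
        raise ValueError(f"count at position {bad} is not an integer: {arr.flat[bad]!r}")
    if np.any(as_int < 1):
        bad = np.flatnonzero(as_int < 1)[0]
        raise ValueError(f"count at position {bad} is < 1: {as_int[bad]}")
    return as_int
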