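import numpy as np
import pytest

from sadkit import Inventory


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def long_csv(tmp_path):
    """Write a small long-format counts file and return its path."""

    def _write(text, name="counts.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def random_counts(rng, max_species=30, max_count=200):
    """A random valid count multiset (>= 1 species, integer counts >= 1)."""
    S = int(rng.integers(1, max_species + 1))
    return rng.integers(1, max_count + 1, size=S)


@pytest.fixture
def random_inventories(rng):
    return [
        Inventory(site_id=f"s{i}", counts=random_counts(rng))
        for i in range(25)
    ]
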