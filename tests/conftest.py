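import numpy as np
import pytest

from coocnet.otu_table import OtuTable
from coocnet.synthetic import BasisSpec, simulate_counts


@pytest.fixture(scope="session")
def planted_dataset():
    """Mid-size community with one strong planted edge, reused read-only."""
    spec = BasisSpec(n_otus=20, planted_edges=((0, 1, 0.8),), seed=42)
    return simulate_counts(spec, 300, 3000)


@pytest.fixture(scope="session")
def null_dataset():
    """Independent OTUs (no planted correlations), reused read-only."""
    spec = BasisSpec(n_otus=10, seed=7)
    return simulate_counts(spec, 200, 2000)


@pytest.fixture()
def small_table():
    rng = np.random.default_rng(5)
    counts = rng.integers(1, 100, size=(12, 6))
    return OtuTable(counts,
                    [f"OTU{i}" for i in range(6)],
                    [f"S{i}" for i in range(12)])
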