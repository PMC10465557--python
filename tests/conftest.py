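import numpy as np
import pytest

from macrogd import synthetic


@pytest.fixture(scope="session")
def small_world():
    """A small 3x3-cell synthetic world shared across read-only tests."""
    spec = synthetic.SyntheticWorld(n_rows=3, n_cols=3, otus_per_cell=12, seed=42)
    return synthetic.generate_world(spec)


@pytest.fixture(scope="session")
def pathology_world(small_world):
    return synthetic.inject_pathologies(small_world, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
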