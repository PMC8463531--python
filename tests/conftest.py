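import numpy as np
import pytest

from microscape.synthetic_data import SyntheticSpec, sample_cross_sectional
from microscape.table_io import CommunityTable


@pytest.fixture
def tiny_table():
    """2 samples x 2 features, counts."""
    return CommunityTable(
        sample_ids=["s1", "s2"],
        feature_ids=["f1", "f2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0]]),
    )


@pytest.fixture
def random_compositions():
    """40 random strictly positive compositional rows over 25 features."""
    rng = np.random.default_rng(7)
    values = rng.dirichlet(np.full(25, 0.8), size=40)
    return CommunityTable(
        sample_ids=[f"s{i}" for i in range(40)],
        feature_ids=[f"f{j}" for j in range(25)],
        values=values,
        is_relative=True,
    )


@pytest.fixture(scope="session")
def k3_dataset():
    """Well-separated 3-archetype cross-sectional fixture with truth."""
    spec = SyntheticSpec(K=3, F=100, n_per_group=30, separation=1.0,
                         concentration=300.0, seed=11)
    return sample_cross_sectional(spec)
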