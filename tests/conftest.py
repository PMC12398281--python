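import numpy as np
import pytest

from gsda.estimator import GroupedDesign
from gsda.synthetic import default_config, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_design(rng, m=40, p=5):
    """A small valid design with both groups and both labels present."""
    X = rng.normal(size=(m, p))
    y = rng.integers(0, 2, size=m)
    g = (np.arange(m) >= m // 2).astype(int)
    # guarantee both labels inside each group
    y[0], y[1] = 0, 1
    y[m // 2], y[m // 2 + 1] = 0, 1
    sids = np.array([f"s{i}" for i in range(m)])
    return GroupedDesign(X, y, g, sids)


@pytest.fixture
def toy_design(rng):
    return random_design(rng, m=20, p=3)


@pytest.fixture(scope="session")
def divergent_dataset():
    """Planted group-divergent synthetic dataset shared across tests."""
    samples, truth = generate(default_config(seed=0, n_subjects_per_group=200))
    return samples, truth


def stack(samples):
    X = np.vstack([s.features for s in samples])
    y = np.asarray([s.hemisphere for s in samples])
    g = np.asarray([s.group for s in samples])
    sid = np.asarray([s.subject_id for s in samples])
    return X, y, g, sid
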