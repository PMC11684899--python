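import numpy as np
import pytest

from dosamo import (
    ClassificationObjective,
    ParsimonyObjective,
    SyntheticSpec,
    generate_classification,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_classification():
    """60 x 100 easy classification dataset (3 informative features)."""
    spec = SyntheticSpec(
        n_samples=60, n_features=100, n_informative=3,
        class_separation=2.0, seed=7,
    )
    data, informative = generate_classification(spec)
    return data, informative


@pytest.fixture
def two_objectives():
    return [
        ClassificationObjective("nb", n_bootstrap=50),
        ParsimonyObjective(cap=100),
    ]


def random_unit_front(rng, n, m, distinct=False):
    """Random fitness matrix in [0,1]^(n x m); optionally distinct coords."""
    if not distinct:
        return rng.uniform(0.05, 0.95, size=(n, m))
    # draw until all per-column coordinates are pairwise distinct
    while True:
        X = rng.uniform(0.05, 0.95, size=(n, m))
        if all(len(np.unique(X[:, j])) == n for j in range(m)):
            return X
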