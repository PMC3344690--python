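import numpy as np
import pytest

from fdiversity import (
    ProbabilityDistribution,
    gini_simpson_generator,
    load_fixture,
    number_of_categories_generator,
    shannon_generator,
)


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def gs():
    return gini_simpson_generator()


@pytest.fixture(scope="session")
def shannon():
    return shannon_generator()


@pytest.fixture(scope="session")
def noc():
    return number_of_categories_generator()


def random_distributions(n, max_k=8, seed=42, min_p=0.0):
    """Seeded Dirichlet(1) draws with k between 2 and max_k."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        k = int(rng.integers(2, max_k + 1))
        p = rng.dirichlet(np.ones(k))
        if min_p and p.min() < min_p:
            continue
        out.append(ProbabilityDistribution([f"c{i}" for i in range(k)], p))
    return out
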