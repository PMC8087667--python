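import numpy as np
import pytest

from scdbm.data_io import CountMatrix
from scdbm.simulate import simulate_nb_mixture, two_cluster_spec


@pytest.fixture(scope="session")
def two_pop():
    """Two well-separated NB populations (n=2000, 50 genes, 10 markers, FC 8)."""
    cm, labels = simulate_nb_mixture(two_cluster_spec(seed=3))
    return cm, labels


@pytest.fixture()
def small_counts():
    rng = np.random.default_rng(0)
    counts = rng.negative_binomial(2.0, 2.0 / 7.0, size=(50, 20))
    return CountMatrix(
        counts,
        [f"c{i}" for i in range(50)],
        [f"g{j}" for j in range(20)],
    )
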