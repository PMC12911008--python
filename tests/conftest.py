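import warnings

import numpy as np
import pytest

import devconn as dc


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="graph is disconnected")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete three-wave cohort shared across tests."""
    spec = dc.CohortSpec(n_baseline=48, n_regions=28, seed=1234,
                         effect_size_connectivity=0.8, effect_size_outcome=0.8)
    return dc.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_graph():
    """Seeded 8-node weighted graph (the brute-force oracle target size)."""
    rng = np.random.default_rng(7)
    a = rng.uniform(0.1, 1.0, size=(8, 8))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    # sparsify to make modules/shortest paths nontrivial
    mask = rng.random((8, 8)) < 0.45
    mask = mask | mask.T
    a = a * mask
    np.fill_diagonal(a, 0)
    return dc.WeightedGraph(a, density=float((a > 0).sum() / (8 * 7)))
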