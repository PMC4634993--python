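import numpy as np
import pytest

from bggm import (
    EdgePrior,
    Graph,
    sample_ground_truth,
    simulate_timeseries,
    standardize_timeseries,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_pd(rng):
    """Factory for random symmetric positive-definite matrices."""

    def make(p, jitter=None):
        a = rng.standard_normal((p, p))
        return a @ a.T + (jitter if jitter is not None else p) * np.eye(p)

    return make


@pytest.fixture(scope="session")
def p3_fixture():
    """A small standardized data set from a known sparse precision (p=3,
    n=200), shared by the enumeration-oracle tests."""
    rng = np.random.default_rng(5)
    G = Graph.from_bitstring("101", 3)  # edges (0,1) and (1,2)
    K, R, truth = sample_ground_truth(G, seed=rng, min_abs_partial=0.25)
    X = standardize_timeseries(simulate_timeseries(K, 200, rng))
    return {"graph": G, "K": K, "R": R, "truth": truth, "X": X,
            "theta": EdgePrior.flat(3, 0.5)}
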