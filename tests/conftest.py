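import numpy as np
import pytest

import connstates as cs


@pytest.fixture(scope="session")
def part21() -> cs.NetworkPartition:
    """21 parcels, 3 per network — smallest size convenient for matrix tests."""
    return cs.make_partition(21)


@pytest.fixture(scope="session")
def part98() -> cs.NetworkPartition:
    """Desk-scale partition used by the study conditions (14 per network)."""
    return cs.make_partition(98)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_connectivity(P: int, seed: int, variant: str = "noGSR") -> cs.ConnectivityMatrix:
    """Correlation matrix of random Gaussian time series (generic fixture)."""
    g = np.random.default_rng(seed)
    X = g.standard_normal((4 * P, P))
    r = np.corrcoef(X, rowvar=False)
    return cs.ConnectivityMatrix(values=r, variant=variant)
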