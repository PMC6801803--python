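import numpy as np
import pytest

from shapefold.fold import fold_mfe
from shapefold.synthetic import (SimulationParams, simulate_reactivities,
                                 simulate_rna)


@pytest.fixture(scope="session")
def small_rna():
    """A 120-nt ground-truth bundle shared across tests."""
    return simulate_rna(120, seed=5, params=SimulationParams(seed=5))


@pytest.fixture(scope="session")
def small_profile(small_rna):
    return simulate_reactivities(small_rna.structure, "SHAPE",
                                 small_rna.params)


@pytest.fixture(scope="session")
def small_dms(small_rna):
    return simulate_reactivities(small_rna.structure, "DMS", small_rna.params)


def random_sequence(rng, n):
    return "".join(rng.choice(list("ACGU"), n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
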