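import numpy as np
import pytest

from cdtaseq import simulator
from cdtaseq.mixturemodel import GlobalParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def params():
    """Batch-level mixture/kinetic parameters used across tests."""
    return GlobalParams(epsilon=1e-3, xi=0.05, t0=1.0, gamma=np.log(2) / 90.0)


@pytest.fixture
def small_cohort(rng):
    """A 20-gene kinetic cohort with seeded log-normal rates."""
    return simulator.default_genes(20, rng)


@pytest.fixture
def toy_references(rng):
    """Small host + spike genomes with one TTS window per gene."""
    return simulator.make_test_references(10, rng)
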