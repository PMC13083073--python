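import numpy as np
import pytest

from plvnet.montage import load_montage
from plvnet.pairs import default_pairset


@pytest.fixture(scope="session")
def montage():
    return load_montage("default30")


@pytest.fixture(scope="session")
def pairset(montage):
    return default_pairset(montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 6-vs-6 theta cohort with the planted effect, shared across tests."""
    from plvnet.synth import CohortSpec, CouplingSpec, generate_cohort

    cohort = CohortSpec(group_sizes={"HC": 6, "PDD": 6}, rng_seed=42)
    coupling = CouplingSpec(band="theta")
    return generate_cohort(cohort, coupling)
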