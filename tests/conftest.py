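import warnings

import pytest

from hzfootprint.core import GenotypeMatrix, LocalityTable, ReferencePanel
from hzfootprint.simulate import (
    StructuredPopScenario,
    ZoneScenario,
    simulate_contact_zone,
    simulate_structured_populations,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """Two individuals at three biallelic loci, one missing call."""
    return GenotypeMatrix(
        ("i1", "i2"),
        ("L1", "L2", "L3"),
        (
            ((("A", "A")), ("A", "B"), ("B", "B")),
            ((("B", "A")), (None, None), ("A", "A")),
        ),
    )


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two diverged populations for clustering tests."""
    scn = StructuredPopScenario(k_true=2, fst=0.3, n_loci=50, n_per_pop=20, seed=3)
    return simulate_structured_populations(scn)


@pytest.fixture(scope="session")
def moving_sim():
    return simulate_contact_zone(ZoneScenario.moving(seed=1))


@pytest.fixture(scope="session")
def stable_sim():
    return simulate_contact_zone(ZoneScenario.stable(seed=1))


@pytest.fixture(scope="session")
def moving_sim_no_enclave():
    return simulate_contact_zone(ZoneScenario(scenario="moving", x0=-100.0, seed=1))


@pytest.fixture(scope="session")
def stable_sim_no_enclave():
    return simulate_contact_zone(ZoneScenario(scenario="stable", seed=1))
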