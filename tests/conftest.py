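import numpy as np
import pytest

from fibrelax.assembly import AssemblyConfig, assemble
from fibrelax.config import PROFILES
from fibrelax.core import Domain, SimParams


@pytest.fixture(scope="session")
def desk_domain() -> Domain:
    d = PROFILES["desk"]["domain"]
    return Domain(**d)


@pytest.fixture(scope="session")
def paper_domain() -> Domain:
    return Domain()


@pytest.fixture
def params() -> SimParams:
    return SimParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_assembly_config() -> AssemblyConfig:
    a = PROFILES["desk"]["assembly"]
    return AssemblyConfig(**a)


@pytest.fixture(scope="session")
def desk_state(desk_domain, desk_assembly_config):
    """One deterministic desk-scale fibrillar matrix shared across tests."""
    return assemble(desk_assembly_config, desk_domain, SimParams(), seed=101)
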