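import numpy as np
import pytest

from migrisk.fixtures import load_fixture
from migrisk.geometry import ContactSystem


@pytest.fixture(scope="session")
def system() -> ContactSystem:
    return ContactSystem()


@pytest.fixture(scope="session")
def table2():
    return load_fixture("migration_params_table2")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("edi_table3")


@pytest.fixture(scope="session")
def rfd_table():
    return load_fixture("rfd_table1")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
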