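import pytest

from lignolink.chem_core import parse_smiles
from lignolink.fingerprints import FingerprintConfig
from lignolink.knowledge import builtin_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """The packaged compound catalog, enzyme map and gene-count annotation."""
    return builtin_fixture()


@pytest.fixture(scope="session")
def path_cfg():
    return FingerprintConfig(scheme="path")


@pytest.fixture(scope="session")
def maccs_cfg():
    return FingerprintConfig(scheme="maccs")


@pytest.fixture
def benzene():
    return parse_smiles("c1ccccc1", "benzene")


@pytest.fixture
def ethanol():
    return parse_smiles("CCO", "ethanol")
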