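import pytest

from dpacs.design import DesignParams
from dpacs.fixtures import load_fixture, mini_enzyme_db


@pytest.fixture(scope="session")
def mini_db():
    return mini_enzyme_db()


@pytest.fixture(scope="session")
def psba():
    return load_fixture("psbA_S264")


@pytest.fixture(scope="session")
def accase():
    return load_fixture("ACCase_I2041")


@pytest.fixture(scope="session")
def epsps():
    return load_fixture("EPSPS_P106")


@pytest.fixture
def tiny_params():
    """Permissive parameters for small synthetic instances."""
    return DesignParams(
        primer_len_min=5,
        primer_len_max=25,
        budget_fw=2,
        budget_rv=2,
        min_resolvability=1,
        extra_budget=0,
    )
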