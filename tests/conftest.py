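import pytest

from phosfit import AcquisitionParams, build_default_basis, default_profile, load_spin_systems
from phosfit.spins import default_linewidths


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def systems():
    return load_spin_systems()


@pytest.fixture(scope="session")
def basis14(acq):
    return build_default_basis(acq)


@pytest.fixture(scope="session")
def lw_table():
    return default_linewidths()


@pytest.fixture(scope="session")
def profile():
    return default_profile()
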