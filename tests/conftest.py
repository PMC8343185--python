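import pytest

from gelwell import GelParams, MotifSpec, PhysicalParams, make_well_geometry, rate_constants
from gelwell.units import motif_count


@pytest.fixture(scope="session")
def phys():
    return PhysicalParams()  # 298 K, 1e-2 Pa*s


@pytest.fixture(scope="session")
def motif():
    return MotifSpec()  # 5 nm, 8 uM


@pytest.fixture(scope="session")
def gel():
    return GelParams()  # rho_g = 14 uM, lambda = 5


@pytest.fixture(scope="session")
def well50():
    return make_well_geometry(50e-6, 100e-6)


@pytest.fixture(scope="session")
def well100():
    return make_well_geometry(100e-6, 100e-6)


@pytest.fixture(scope="session")
def rates50(phys, motif, well50):
    return rate_constants(phys, motif, well50)


@pytest.fixture(scope="session")
def n0_8uM_50(well50):
    return motif_count(8e-6, well50.volume)
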