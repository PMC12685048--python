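import numpy as np
import pytest

from phytoswitch import photokinetics as pk
from phytoswitch import units


@pytest.fixture(scope="session")
def flux_1kw_660():
    return units.photon_flux_from_irradiance(1000.0, 660.0)


@pytest.fixture()
def solution_params():
    """In-vitro style parameter set: Q-band extinction, no thermal recovery."""
    return pk.SwitchingParameters(
        phi_off=0.03,
        phi_on=0.01,
        eps_pr=pk.ExtinctionSpectrum.constant(86100.0),
        eps_pfr=pk.ExtinctionSpectrum.constant(25000.0),
    )


@pytest.fixture()
def off_only_params():
    """Pure off-switching: no on-switching, Pfr transparent."""
    return pk.SwitchingParameters(
        phi_off=0.03,
        phi_on=0.0,
        eps_pr=pk.ExtinctionSpectrum.constant(86100.0),
        eps_pfr=pk.ExtinctionSpectrum.constant(0.0),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
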