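import numpy as np
import pytest

from padkin.flow import ChannelGeometry, FluidProperties, SimUnitScaling


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def channel():
    """The assay's nominal rectangular channel: 19 x 1 x 0.1 mm."""
    return ChannelGeometry(length=19e-3, width=1e-3, h0=1e-4)


@pytest.fixture
def water37():
    """Water at 37 C: rho = 993.36 kg/m^3, eta = 0.6922 mPa s."""
    return FluidProperties(rho=993.36, eta=6.922e-4, temperature_c=37.0)


@pytest.fixture
def lattice_scaling():
    """Lattice-unit scaling: r_sim = 16 lattice units for a 1.5 um bead,
    nu_sim = 1 at the reference flow rate."""
    return SimUnitScaling(r_sim=16.0, nu_sim=1.0, r_si=1.5e-6, nu_si=6.968e-7)
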