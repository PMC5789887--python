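import numpy as np
import pytest

from qens_bilayer.grids import default_energy_grid
from qens_bilayer.models import (
    FluidModelParams,
    GelCoagelModelParams,
    sphere_eigenvalues,
)


@pytest.fixture(scope="session")
def eig():
    """Shared reflecting-sphere eigenvalue table."""
    return sphere_eigenvalues()


@pytest.fixture(scope="session")
def grid():
    return default_energy_grid()


@pytest.fixture
def coagel_params():
    """Ordered-phase parameters as reported for the coagel at 315 K."""
    return GelCoagelModelParams(p_x=0.15, a=1.7, tau=2.45, tau_MG=6.7)


@pytest.fixture
def gel_params():
    """Gel-phase parameters (308 K): p_x = 0.64, a = 1.8 Å."""
    return GelCoagelModelParams.from_d_r(p_x=0.64, a=1.8, d_r_per_ps=0.068,
                                         tau_MG=5.2)


@pytest.fixture
def fluid_params():
    """Fluid-phase parameters at 345 K (diffusivities in Å²/ps)."""
    return FluidModelParams(r_min=0.1, r_max=5.4, d_min=6e-3, d_max=0.261,
                            tau_MG=2.6)
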