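import math

import numpy as np
import pytest

from lclcsense.optics import CellOptics, DispersionModel, default_dscg_dispersion


@pytest.fixture(scope="session")
def dispersion():
    return default_dscg_dispersion()


@pytest.fixture
def planar_cell(dispersion):
    """15-um planar cell, director along the analyzer axis."""
    return CellOptics(gap_d=15000.0, pretilt_theta=0.0, azimuth_phi=0.0,
                      dispersion=dispersion)


@pytest.fixture
def grid400():
    return np.linspace(400.0, 800.0, 400)


def constant_dispersion(n_par: float, n_perp: float) -> DispersionModel:
    """Dispersionless index pair (B = 0), handy for closed-form checks."""
    return DispersionModel(n_parallel_coeffs=(n_par, 0.0),
                           n_perp_coeffs=(n_perp, 0.0))


@pytest.fixture
def tilted_cell_factory(dispersion):
    def make(phi_deg: float, theta_deg: float = 0.0,
             gap: float = 15000.0) -> CellOptics:
        return CellOptics(gap_d=gap, pretilt_theta=math.radians(theta_deg),
                          azimuth_phi=math.radians(phi_deg),
                          dispersion=dispersion)
    return make
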