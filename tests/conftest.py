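"""Shared fixtures: materials, layer systems, traced branches, spectra.

Expensive artifacts (mode traces, synthetic spectra, one FD wavefield) are
session-scoped so the suite builds each once.
"""

from __future__ import annotations

import numpy as np
import pytest

from nitiwave.dispersion import LayerSystem, trace_a0
from nitiwave.materials import make_material
from nitiwave.processing import spectrum2d
from nitiwave.wavefield import simulate_fd, synthesize_modal

# canonical anisotropic cornea-like parameters: G = 20 kPa, mu = 5G
G_TRUE = 20e3
MU_TRUE = 100e3
H_TRUE = 0.55e-3


@pytest.fixture(scope="session")
def mat_aniso():
    return make_material(mu=MU_TRUE, G=G_TRUE, rho=1000.0, cL=1540.0)


@pytest.fixture(scope="session")
def sys_aniso(mat_aniso):
    return LayerSystem(material=mat_aniso, h=H_TRUE)


@pytest.fixture(scope="session")
def mat_iso():
    return make_material(mu=G_TRUE, G=G_TRUE, rho=1000.0, cL=1540.0)


@pytest.fixture(scope="session")
def sys_iso(mat_iso):
    return LayerSystem(material=mat_iso, h=H_TRUE)


@pytest.fixture(scope="session")
def a0_aniso(sys_aniso):
    """A0 branch of the anisotropic layer over the full synthesis band."""
    return trace_a0(sys_aniso, np.geomspace(100.0, 8000.0, 40))


@pytest.fixture(scope="session")
def xt_aniso(a0_aniso):
    """Noiseless A0-only synthetic wavefield on the OCE sampling grids."""
    return synthesize_modal([a0_aniso])


@pytest.fixture(scope="session")
def spec_aniso(xt_aniso):
    return spectrum2d(xt_aniso)


@pytest.fixture(scope="session")
def fd_field(sys_aniso):
    """One finite-difference wavefield shared by the FD-sanity tests."""
    return simulate_fd(
        sys_aniso,
        points_per_wavelength=20,
        domain_length=16e-3,
        duration=9e-3,
    )
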