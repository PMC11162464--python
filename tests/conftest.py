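import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eetkit import SynthConfig, make_nadh_model, propagate
from eetkit.synthetic_data import make_nadh_basis
from eetkit.vibronic_model import BasisSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    """The frozen donor/CT/acceptor fixture (CT 0.5 eV below the donor)."""
    return make_nadh_model(SynthConfig())


@pytest.fixture(scope="session")
def default_basis():
    return make_nadh_basis(SynthConfig())


@pytest.fixture(scope="session")
def default_trajectory(default_model, default_basis):
    """200 fs Franck-Condon propagation of the default model (shared because
    it is the most expensive fixture in the suite)."""
    return propagate(default_model, default_basis, t_final=200.0, dt_out=0.5,
                     initial_state="La")


@pytest.fixture(scope="session")
def mini_config():
    """Two-mode variant of the generator for cheap ensemble propagations."""
    return SynthConfig(tuning_frequencies=(1500.0,), n_coupling_modes=1,
                       coupling_band=(400.0, 400.0))


@pytest.fixture(scope="session")
def mini_model(mini_config):
    return make_nadh_model(mini_config)


@pytest.fixture(scope="session")
def mini_basis():
    return BasisSpec(np.array([10, 16]))


def mini_with_ct_offset(mini_model, offset_ev):
    """Copy of the mini model with the CT state moved to La + offset."""
    E = mini_model.E.copy()
    E[1] = E[0] + offset_ev
    return dataclasses.replace(mini_model, E=E)
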