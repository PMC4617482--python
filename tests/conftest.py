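import numpy as np
import pytest

import condrobust as cr
from condrobust.models import DynamicalModel, PiecewiseConstantInput


@pytest.fixture(scope="session")
def pulse_model():
    return cr.pulse_generator_model()


@pytest.fixture(scope="session")
def pulse_space(pulse_model):
    return cr.build_parameter_space(pulse_model.nominal_parameters)


@pytest.fixture(scope="session")
def nominal_pulse_trajectory(pulse_model):
    params = [pulse_model.nominal_parameters[n] for n in pulse_model.parameter_names]
    return cr.integrate_model(pulse_model, params)


@pytest.fixture(scope="session")
def decay_model():
    """One-state linear decay dx/dt = -r x with x(0) = 1."""
    return DynamicalModel(
        name="decay",
        state_names=("x",),
        parameter_names=("r",),
        rhs=lambda x, t, p, u: (-p[0] * x[0],),
        initial_state=(1.0,),
        inputs=PiecewiseConstantInput.constant((), ()),
        nominal_parameters={"r": 1.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
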