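import numpy as np
import pytest

from labferm import (
    GeneratorConfig,
    SolverConfig,
    StoichiometryConstants,
    control_parameters,
    default_initial_conditions,
    p_acidilactici_parameters,
    simulate,
)


@pytest.fixture(scope="session")
def stoich():
    return StoichiometryConstants()


@pytest.fixture(scope="session")
def control_p():
    return control_parameters()


@pytest.fixture(scope="session")
def pa_p():
    return p_acidilactici_parameters()


@pytest.fixture(scope="session")
def control_y0():
    return default_initial_conditions("control")


@pytest.fixture(scope="session")
def pa_y0():
    return default_initial_conditions("p_acidilactici")


@pytest.fixture(scope="session")
def control_traj(control_p, control_y0):
    """Noiseless collocation trajectory of the control batch on the study grid."""
    return simulate(control_p, None, control_y0)


@pytest.fixture(scope="session")
def dense_cfg():
    """Hourly output grid for trajectory-shape assertions."""
    grid = tuple(np.linspace(0.0, 60.0, 121))
    return SolverConfig(t_grid=grid)


@pytest.fixture(scope="session")
def control_obs_lownoise():
    """Control-batch observations at 1%-of-range noise, triplicates."""
    from labferm import generate

    cfg = GeneratorConfig(batch="control", noise_frac_of_range=0.01, seed=2024)
    obs, traj = generate(cfg, return_trajectory=True)
    return cfg, obs, traj
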