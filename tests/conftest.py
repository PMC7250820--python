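import pytest

import periphos as pp


@pytest.fixture(scope="session")
def fig3_params() -> pp.KineticParameters:
    return pp.fig3_default_parameters()


@pytest.fixture(scope="session")
def fig3_design() -> pp.ExperimentDesign:
    return pp.fig3_default_design()


@pytest.fixture(scope="session")
def fig3_trajectory(fig3_params, fig3_design) -> pp.Trajectory:
    """The reference pulse-chase simulation, shared across tests."""
    return pp.simulate(fig3_params, fig3_design)
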