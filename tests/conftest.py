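import numpy as np
import pytest

from biosos.network import (
    CultureCondition,
    default_network,
    simulate_monolayer,
)


@pytest.fixture(scope="session")
def model():
    return default_network()


@pytest.fixture(scope="session")
def hgll_condition():
    """High-glucose low-lactate monolayer condition (historic-style)."""
    return CultureCondition(
        initial_concentrations={"EGLC": 18.3, "EGLN": 2.7, "ELAC": 0.0, "EPYR": 0.41},
        initial_vcd=3.2e4,
        duration_h=48.0,
        label="historic-HGLL",
    )


@pytest.fixture(scope="session")
def hgll_trajectory(model, hgll_condition):
    return simulate_monolayer(model, hgll_condition, np.linspace(0, 48, 13))
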