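import numpy as np
import pytest

from respcpg import ModelParameters, SolverSettings, StimulusProtocol, integrate_model
from respcpg.analysis import cycle_metrics, detect_bursts


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline_trace(params):
    """Unstimulated 60 s run with default settings (shared across tests)."""
    return integrate_model(params, StimulusProtocol(), (0.0, 60000.0))


@pytest.fixture(scope="session")
def baseline_bursts(baseline_trace):
    """Bursts detected past the 20 s transient."""
    return detect_bursts(baseline_trace, t_start=20000.0)


@pytest.fixture(scope="session")
def baseline_metrics(baseline_bursts):
    return cycle_metrics(baseline_bursts)
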