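import numpy as np
import pytest

from touchzap import CircuitParams, StepProtocol, simulate_step_response


@pytest.fixture
def step():
    return StepProtocol(onset_s=0.25, duration_s=0.5, amplitude_na=-0.1)


@pytest.fixture
def neuron_params():
    """Cohort-typical neuron with a modest uncompensated bridge residual."""
    return CircuitParams(R_in=100.0, tau_m=10.0, E_rest=-70.0,
                         tau_e=0.1, bridge_error=20.0)


@pytest.fixture
def clean_trace(step):
    """Noiseless single-exponential response (no electrode artifact)."""
    p = CircuitParams(R_in=100.0, tau_m=10.0, E_rest=-70.0, tau_e=0.0, bridge_error=0.0)
    return simulate_step_response(p, step)


def make_trace(step=None, sampling_rate=40_000.0, seed=None, **params):
    step = step or StepProtocol(onset_s=0.25, duration_s=0.5, amplitude_na=-0.1)
    defaults = dict(R_in=100.0, tau_m=10.0, E_rest=-70.0, tau_e=0.0, bridge_error=0.0)
    defaults.update(params)
    return simulate_step_response(CircuitParams(**defaults), step, sampling_rate, seed=seed)
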