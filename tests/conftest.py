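import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from canoncircuit import (
    MeasurementWindows,
    baseline_state,
    build_network,
    default_protocol,
    integrate,
    measure_activity,
    reference_params,
)

# Simulations in the suite use a 1 ms step unless the test is specifically
# about step-size convergence; the convergence test bounds the error this
# introduces.
DT = 1e-3


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def ref_net(ref_params):
    return build_network(ref_params)


@pytest.fixture(scope="session")
def ref_baseline(ref_net):
    """Baseline equilibrium state (V, gains) of the reference network."""
    return baseline_state(ref_net)


@pytest.fixture(scope="session")
def ref_pulse_result(ref_net, ref_baseline):
    """Reference single-pulse run: 200 ms pulse to exc_a at 5 s, 16 s total."""
    V0, g0 = ref_baseline
    return integrate(ref_net, default_protocol(ref_net), dt=DT, seed=None,
                     V0=V0, gains0=g0)


@pytest.fixture(scope="session")
def ref_summary(ref_pulse_result):
    return measure_activity(ref_pulse_result, MeasurementWindows())
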