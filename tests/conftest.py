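import numpy as np
import pytest

from cbgt import DecisionCircuit, TrialProtocol


SMALL_SIZES = {
    "CxI": 37, "Cx": 41, "dSPN": 15, "iSPN": 15, "FSI": 15,
    "GPi": 15, "GPe": 150, "STN": 150, "Th": 15,
}


@pytest.fixture(scope="session")
def control_circuit():
    """The control network (control conductance table), one anatomy."""
    return DecisionCircuit(connectivity_seed=42)


@pytest.fixture(scope="session")
def control_session(control_circuit):
    """One 300-trial session of the control network (shared by slow tests)."""
    summary, trials = control_circuit.run_session(
        TrialProtocol(), n_trials=300, seed=20260)
    return summary, trials


@pytest.fixture(scope="session")
def small_circuit():
    """A down-scaled circuit for structural/kinetic checks (not behavior)."""
    return DecisionCircuit(sizes=SMALL_SIZES, connectivity_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
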