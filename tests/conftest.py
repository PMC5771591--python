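import numpy as np
import pytest
from hypothesis import settings

from cardiomef.tnnp import CellParams, StimulusSpec, equilibrate, run_paced_cell
from cardiomef.sac import SacParams

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cell_params():
    return CellParams()


@pytest.fixture(scope="session")
def sac_params():
    return SacParams()


@pytest.fixture(scope="session")
def rest_state(cell_params):
    """Quiescent resting point of the unstretched cell (8 s relaxation)."""
    return equilibrate(cell_params, None, 1.0, duration=8000.0)


@pytest.fixture(scope="session")
def control_ap(cell_params, rest_state):
    """Single 52 pA/pF x 1 ms stimulated beat from rest (600 ms window)."""
    return run_paced_cell(cell_params, StimulusSpec(), duration=600.0,
                          initial_state=rest_state)


@pytest.fixture(scope="session")
def cai_1hz(cell_params, rest_state):
    """Last-beat Ca transient of a 6-beat 1 Hz train, sampled at 0.02 ms."""
    tr = run_paced_cell(cell_params, StimulusSpec(period=1000.0),
                        duration=6000.0, initial_state=rest_state,
                        record_stride=0.02)
    return tr.cai[-50000:]


def apd_at_threshold(t, vm, threshold=-60.0):
    """APD as the span of samples above the threshold (test helper)."""
    idx = np.where(vm > threshold)[0]
    if idx.size == 0 or vm[-1] > threshold:
        return None
    return t[idx[-1]] - t[idx[0]]
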