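import numpy as np
import pytest

import cvinfer as cv
from cvinfer.series import ObservableSeries


@pytest.fixture(scope="session")
def reference_params():
    """The printed neonate-like simulation parameter set."""
    return cv.SIMULATION_REFERENCE


@pytest.fixture(scope="session")
def neonate_meta():
    return cv.PatientMeta(age_years=14.0 / 365.0, weight_kg=3.5)


@pytest.fixture(scope="session")
def control_trace():
    """Control-scenario trajectory, shared across tests (read-only)."""
    return cv.simulate(scenario="control")


@pytest.fixture(scope="session")
def control_obs(control_trace):
    return control_trace.observables()


@pytest.fixture(scope="session")
def hypovolemic_trace():
    return cv.simulate(scenario="hypovolemic")


@pytest.fixture
def constant_obs():
    """A flat observable envelope for waveform round-trips."""
    t = np.arange(0.0, 60.0001, 0.1)
    ones = np.ones_like(t)
    return ObservableSeries(t, 100.0 * ones, 5.0 * ones, 120.0 * ones,
                            40.0 * ones, 1.0 * ones)
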