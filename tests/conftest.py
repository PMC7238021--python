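import numpy as np
import pytest

from quetsim import PDPopulationSpec, PKPopulationSpec, typical_patient


@pytest.fixture(scope="session")
def pk_spec():
    return PKPopulationSpec()


@pytest.fixture(scope="session")
def pd_spec():
    return PDPopulationSpec()


@pytest.fixture(scope="session")
def typical(pk_spec, pd_spec):
    return typical_patient(pk_spec, pd_spec)


def steady_state_cp(t_in_interval, dose, tau, ka, ke, v):
    """Closed-form steady-state concentration (geometric-series limit of the
    superposed one-compartment profile); independent oracle for the
    brute-force engine."""
    t = np.asarray(t_in_interval, float)
    amp = dose * ka / (v * (ka - ke))
    return amp * (
        np.exp(-ke * t) / (1.0 - np.exp(-ke * tau))
        - np.exp(-ka * t) / (1.0 - np.exp(-ka * tau))
    )
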