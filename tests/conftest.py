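import numpy as np
import pytest

from bercvr import gas, synthetic

#: generator settings with every stochastic perturbation switched off
NOISELESS = dict(noise_sd=0.0, vent_noise_frac=0.0, gas_noise_mmHg=0.0,
                 breath_period_sd=0.0, bh_drift_cv_co2=0.0, bh_drift_cv_o2=0.0,
                 bh_duration_sd_s=0.0, tob_recovery_gain=0.0)


@pytest.fixture(scope="session")
def protocol():
    return synthetic.generate_protocol(seed=1)


@pytest.fixture(scope="session")
def noiseless_params():
    return synthetic.GasSimParams(seed=1, **NOISELESS)


@pytest.fixture(scope="session")
def noiseless_traces(protocol, noiseless_params):
    return synthetic.simulate_gas_traces(protocol, noiseless_params)


@pytest.fixture(scope="session")
def noiseless_rge(protocol, noiseless_traces):
    breaths = gas.detect_breath_markers(noiseless_traces,
                                        resp=noiseless_traces.resp)
    return gas.compute_rge_metrics(breaths)


@pytest.fixture(scope="session")
def noisy_subject():
    """One realistic subject simulated end to end (shared, read-only)."""
    from bercvr import study
    return study.simulate_subject(seed=42,
                                  table_row=synthetic.MRI_SESSION_SUBJECTS[1])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
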