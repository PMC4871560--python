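import numpy as np
import pytest

import pupilfir as pf


@pytest.fixture(scope="session")
def canonical():
    return pf.canonical_kernels("table1")


@pytest.fixture(scope="session")
def noisefree_session():
    """One deterministic kernels-only session (no noise/dropout/drift)."""
    spec = pf.ExperimentSpec(
        run_duration=300.0, noise_sd=0.0, dropout=False, beta=0.0,
        tonic_amplitude=0.0, subject_gain_cv=0.0, subject_latency_cv=0.0,
        subject_shape_sd=0.0,
    )
    ts, truth = pf.simulate_session(spec, 12345)
    return ts, truth


@pytest.fixture(scope="session")
def default_session():
    """One session under the full default study conditions."""
    spec = pf.ExperimentSpec()
    ts, truth = pf.simulate_session(spec, 2024)
    return ts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
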