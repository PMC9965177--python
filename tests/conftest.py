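import numpy as np
import pytest

from alesense import AnalysisConfig, SimConfig, analyze_series, simulate_run


@pytest.fixture(scope="session")
def default_run():
    """Full 22-batch evolution run under the default study conditions."""
    return simulate_run(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_run):
    return analyze_series(default_run.series, AnalysisConfig(mu_reference=0.61))


@pytest.fixture(scope="session")
def short_run():
    """Three batches with default measurement noise."""
    return simulate_run(SimConfig(seed=5, n_batches=3))


@pytest.fixture(scope="session")
def noiseless_run():
    """Three batches with every stochastic measurement effect off."""
    return simulate_run(SimConfig(seed=2, n_batches=3).noiseless())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
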