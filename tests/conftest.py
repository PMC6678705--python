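import numpy as np
import pytest

from seiraquant import BaselineConfig, WavenumberPanel
from seiraquant.synthetic import SimTruth, default_designs, simulate_experiment

GRID = 900.0 + np.arange(301.0)


@pytest.fixture(scope="session")
def grid():
    return GRID.copy()


@pytest.fixture(scope="session")
def panel():
    return WavenumberPanel()


@pytest.fixture(scope="session")
def baseline_config():
    return BaselineConfig()


@pytest.fixture(scope="session")
def noiseless_truth():
    """Default 4-line truth with replicate noise switched off."""
    return SimTruth(noise_sigma=0.0)


@pytest.fixture(scope="session")
def separated_truth():
    """3 well-separated lines, zero noise: the exact-recovery configuration."""
    return SimTruth.separated(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Default study conditions: 3 cycles x 11 sets x 30 replicates, sigma=0.002."""
    return simulate_experiment(truth=SimTruth(), seed=20260925)


@pytest.fixture(scope="session")
def small_experiment():
    """Reduced-replicate noisy experiment for cheaper tests."""
    return simulate_experiment(
        designs=default_designs(replicates_per_set=5), truth=SimTruth(), seed=11)
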