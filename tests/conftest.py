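import numpy as np
import pytest

from poolscreen import AntibodyMatrix, SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_matrix():
    """20 cases + 20 controls, 6 antibodies, fixed seed."""
    rng = np.random.default_rng(12345)
    outcomes = (rng.random((40, 6)) < 0.25).astype(np.int8)
    labels = np.array([1] * 20 + [0] * 20, dtype=np.int8)
    return AntibodyMatrix(outcomes=outcomes, labels=labels)


@pytest.fixture
def small_cohort():
    """Simulated cohort at reduced antibody count, library-default arms."""
    return simulate_cohort(SimulationConfig(n_antibodies=300, n_signal=50, seed=777))
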