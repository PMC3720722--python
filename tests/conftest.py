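import numpy as np
import pytest

from iegdyn import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def study_config():
    """Default study design: 33 genes, 3 replicas, 12 points in [10, 95] min."""
    return simulate.SimulationConfig(seed=7)


@pytest.fixture
def planted_timecourses(study_config):
    tcs, labels = simulate.generate_timecourses(study_config, [13, 14, 6])
    return tcs, labels
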