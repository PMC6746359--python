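import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from bayesdr.simulation_study import DGPParams, generate_sim_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def dgp_dataset():
    """One simulated confounded dataset at the study's default settings."""
    return generate_sim_dataset(DGPParams(), np.random.default_rng(7))


@pytest.fixture
def toy_linear():
    """Six rows generated exactly from y = 1 + 2 d + 3 x (no noise)."""
    from bayesdr.data_model import ObservationalDataset

    x = np.array([0.0, 1.0, 2.0, -1.0, 0.5, 3.0])
    d = np.array([1, 0, 1, 0, 1, 0])
    y = 1.0 + 2.0 * d + 3.0 * x
    return ObservationalDataset(y, d, x[:, None], ("x",))
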