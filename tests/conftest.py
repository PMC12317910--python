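import numpy as np
import pytest

from aftfuse.data import SurvivalDataset
from aftfuse.simulate import SimulationConfig, generate


@pytest.fixture
def tiny_dataset() -> SurvivalDataset:
    """Five subjects, two covariates, mixed censoring and sources."""
    return SurvivalDataset(
        time=np.array([2.0, 1.0, 3.0, 0.5, 4.0]),
        event=np.array([1, 0, 1, 1, 0]),
        treatment=np.array([1, 0, 1, 0, 1]),
        source=np.array([1, 1, 0, 0, 0]),
        covariates=np.array([[0.1, -1.0], [0.5, 0.2], [-0.3, 1.5], [1.0, 0.0], [-0.7, -0.2]]),
    )


@pytest.fixture(scope="session")
def sim_small():
    """One small confounded replicate with moderate censoring."""
    config = SimulationConfig(n=600, p=10, confounded=True, censor_rate=0.2, seed=7)
    dataset, truth = generate(config)
    return config, dataset, truth
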