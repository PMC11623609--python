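import numpy as np
import pytest

from palace.sim import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """A minimal but complete dataset shared by integration-level tests."""
    cfg = SimConfig(
        seed=101,
        n_participants=3,
        n_searchlights=4,
        vertices_per_searchlight=20,
        signal_searchlight_fraction=0.5,
        n_guided_runs=2,
        beta_direct=0.6,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
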