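import numpy as np
import pytest

from pemnet.synthetic_data import make_benchmark


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_state():
    """Small easy benchmark shared across modules: 8k frames, 2 states."""
    return make_benchmark("two_state_easy", n_traj=20, n_frames=400, seed=7)


@pytest.fixture(scope="session")
def twelve_state():
    """Mirror-pair benchmark: 12 planted states in 6 (i, i') pairs."""
    return make_benchmark("twelve_state_mirror", n_traj=20, n_frames=400, seed=7)
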