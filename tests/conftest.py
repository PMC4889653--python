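import numpy as np
import pytest

from eprr.estimator import ModelCache


@pytest.fixture(scope="session")
def session_cache() -> ModelCache:
    """One model cache for the whole run, as a genome scan would use."""
    return ModelCache(seed=20260928, training_reps=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
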