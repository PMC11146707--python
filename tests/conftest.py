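import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_binary_dataset():
    """60 balanced AF/normal 10-s segments at 250 Hz (shared, read-only)."""
    from afmsdc.ecgsim import make_dataset

    return make_dataset(30, ("af", "normal"), 250.0, 10.0, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
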