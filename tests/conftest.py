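import numpy as np
import pytest

from sirenstack import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_truth():
    """A small dendrite phantom with spines, shared across read-only tests."""
    return generate_phantom(PhantomSpec(shape=(8, 32, 32), n_dendrites=2,
                                        n_spines=4, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
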