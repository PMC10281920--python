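import numpy as np
import pytest

from cpemip.phantom import PhantomSpec, generate_phantom

SMALL = dict(shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def neg_study():
    """A small negative phantom study (volume, ground-truth mask, record)."""
    return generate_phantom(PhantomSpec(label="NEG", seed=11, **SMALL))


@pytest.fixture(scope="session")
def cpe_study():
    return generate_phantom(PhantomSpec(label="CPE", seed=12, **SMALL))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
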