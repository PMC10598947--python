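import numpy as np
import pytest

from m3mc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom (buccal relation, default geometry)."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def lingual_phantom():
    return generate_phantom(PhantomSpec(relation="lingual", seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
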