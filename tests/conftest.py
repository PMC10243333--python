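import numpy as np
import pytest

from renalscint.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=123)


@pytest.fixture(scope="session")
def default_case(default_spec):
    """One seeded 64x64, 10-frame phantom shared across read-only tests."""
    return generate_phantom(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
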