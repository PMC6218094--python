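import numpy as np
import pytest

from redoxqc import fixtures as fix


@pytest.fixture(scope="session")
def bundle():
    """One deterministic synthetic study shared across the suite."""
    return fix.generate_fixture_bundle(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
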