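import numpy as np
import pytest

from oxyfun import synthgen
from oxyfun.synthgen import ToySiteSpec


@pytest.fixture(scope="session")
def toy_site():
    return synthgen.make_toy_site(ToySiteSpec(seed=1))


@pytest.fixture(scope="session")
def reference(toy_site):
    return synthgen.make_reference_complex(toy_site)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
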