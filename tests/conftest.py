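import numpy as np
import pytest
from hypothesis import settings

from hemoquant.spectra import build_component_library

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return build_component_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240521)
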