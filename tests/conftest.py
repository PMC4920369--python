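import numpy as np
import pytest

from genecue.core import Dimorphism, ModelParams


@pytest.fixture(scope="session")
def reference_params():
    """Standard parameter set: N=(20,2), W=0.5, b=3.0, c=1.5, m=0.05."""
    return ModelParams.reference(m=0.05, rho=0.0)


@pytest.fixture(scope="session")
def sample_dimorphism():
    return Dimorphism(z1=0.2, z2=0.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
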