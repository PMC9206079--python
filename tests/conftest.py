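import numpy as np
import pytest

from gluquanta.kernel import make_unitary_kernel


@pytest.fixture(scope="session")
def kernel():
    """Standard unitary response: tau 68 ms sampled at 4 ms/frame."""
    return make_unitary_kernel(tau=68.0, frame_interval=4.0, length=256)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
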