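import numpy as np
import pytest

import rgcsnn.autograd as ag


@pytest.fixture
def float64_tape():
    """Run the tape in float64 for finite-difference gradient checks."""
    ag.set_dtype(np.float64)
    yield
    ag.set_dtype(np.float32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_wounds():
    """A small deterministic synthetic wound set shared across tests."""
    from rgcsnn.synthetic import SynthConfig, generate

    return generate(SynthConfig(n_images=6, size=32, seed=42))
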