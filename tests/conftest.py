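import numpy as np
import pytest

from neoquant import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_spec():
    return synthgen.CohortSpec()


@pytest.fixture(scope="session")
def short_recording():
    """5 simulated minutes of default discontinuous LFP with truth."""
    spec = synthgen.CohortSpec(duration_s=300.0, fs=1000.0)
    return synthgen.gen_recording(spec, n_channels=2, seed=7)


@pytest.fixture(scope="session")
def microglia_stack():
    """Default two-channel synthetic stack with planted truth."""
    return synthgen.gen_microglia_stack(
        n_cells=5, n_puncta_inside=8, n_puncta_outside=5, seed=11
    )
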