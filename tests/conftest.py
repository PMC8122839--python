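import logging

import numpy as np
import pytest

from earpipe.stimuli import OddballSpec
from earpipe.synth import ArtifactSpec, simulate_oddball_recording

logging.getLogger("earpipe").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def contaminated_recording():
    """One default-scenario oddball recording with artifacts and its log."""
    return simulate_oddball_recording(seed=1234, artifacts=ArtifactSpec())


@pytest.fixture(scope="session")
def short_oddball_spec():
    """A 10-sequence oddball paradigm for faster pipeline tests."""
    return OddballSpec(n_sequences=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
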