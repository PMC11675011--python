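import numpy as np
import pytest

from socoh.behavior import ChamberGeometry
from socoh.simulate import CohortSpec


@pytest.fixture(scope="session")
def geom():
    return ChamberGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast cohort spec for structural tests (2 + 2 animals, 2 min)."""
    return CohortSpec(n_sham=2, n_tbi=2, session_s=120.0, seed=7)


@pytest.fixture(scope="session")
def short_session_spec():
    """Single-animal-scale spec with the default effect structure."""
    return CohortSpec(session_s=120.0, seed=7)
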