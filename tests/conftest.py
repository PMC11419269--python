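import numpy as np
import pytest
from hypothesis import settings

from trem2map.hydropathy import kyte_doolittle
from trem2map.io import load_segments, packaged_sequences
from trem2map.kinetics import PhaseSchedule

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scale():
    return kyte_doolittle()


@pytest.fixture(scope="session")
def sequences():
    return packaged_sequences()


@pytest.fixture(scope="session")
def segments():
    return load_segments()


@pytest.fixture
def short_schedule():
    """A quick-to-simulate phase schedule for fitting tests."""
    return PhaseSchedule(baseline=10, association=300, dissociation=300, dt=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20241)
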