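import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cardiomar.phantom import ArtifactSpec, PhantomSpec, make_case


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom grid used where full study scale is unnecessary."""
    return PhantomSpec(shape=(48, 48, 24), noise_sd_hu=5.0)


@pytest.fixture(scope="session")
def case_pool():
    """A handful of full-scale phantom cases shared across tests."""
    return [make_case(s) for s in range(4)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
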