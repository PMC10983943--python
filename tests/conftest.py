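import numpy as np
import pytest

from editaudit.records import Genome
from editaudit.synthetic import generate_genome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """A 3-kb random circular genome used across scanner/proximity tests."""
    return generate_genome(3000, 0.5, seed=101)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240319)
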