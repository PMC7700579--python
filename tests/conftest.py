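import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from agglomnet import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(n_regions=12, n_indicators=5, years=(2018,), seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def default_dataset():
    return generate(SyntheticSpec(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
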