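import numpy as np
import pytest

from goodph import synthetic as syn


@pytest.fixture(scope="session")
def tables():
    return syn.make_fixture_models(1)


@pytest.fixture(scope="session")
def composite(tables):
    return syn.make_composite(tables)


@pytest.fixture(scope="session")
def composite_ext(tables):
    return syn.make_composite(tables, include_penicillin=True)


@pytest.fixture
def window_grid():
    return np.arange(2700.0, 3101.0, 1.0)


@pytest.fixture
def quiet_noise():
    """Zero-noise configuration (still seeded, as required)."""
    return syn.NoiseConfig(0.0, 0.0, 0.0, seed=0)
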