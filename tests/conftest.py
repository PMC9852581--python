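import numpy as np
import pytest

from wearstd.synthetic import BoutSpec, FixtureSpec, generate_subject


@pytest.fixture
def free_living_fixture():
    """Default free-living subject: clean, spurious, and incline bouts."""
    spec = FixtureSpec(seed=101)
    dataset, truth = generate_subject(spec)
    return spec, dataset, truth


@pytest.fixture
def small_spec():
    """Short fixture for fast I/O tests: one 4-stride bout, ~25 s of signal."""
    return FixtureSpec(seed=202, bouts=(BoutSpec(start=5.0, n_strides=4),), duration=15.0)


@pytest.fixture
def rng():
    return np.random.default_rng(4242)
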