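import numpy as np
import pytest

from loinmri import PhantomSpec, load_fresh_loin_ccd


@pytest.fixture(scope="session")
def ccd():
    """Packaged 13-run fresh-loin design and its five responses."""
    return load_fresh_loin_ccd()


@pytest.fixture
def small_spec():
    """A compact phantom spec used where full-size slices are unnecessary."""
    return PhantomSpec(height=80, width=100, ellipse_center=(40.0, 50.0),
                       ellipse_axes=(30.0, 40.0), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
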