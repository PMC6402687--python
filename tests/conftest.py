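import numpy as np
import pytest
from hypothesis import settings

from phasecell.fixtures import make_arrays, make_frame
from phasecell.image_io import CLASS_LABELS

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_crop_bank():
    """(images, labels) with 20 crops per class; shared across tests."""
    return make_arrays({c: 20 for c in CLASS_LABELS}, seed=11)


@pytest.fixture(scope="session")
def fixture_frame():
    """One 600x800 frame with 3 well-separated cells plus its oracle."""
    frame, mask, params = make_frame(3, rng=0)
    return frame, mask, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
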