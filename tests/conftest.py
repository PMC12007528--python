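import numpy as np
import pytest
from scipy import ndimage

from dianasim import SequenceParams, make_default_phantom
from dianasim.phantom import baseline_image


@pytest.fixture(scope="session")
def seq():
    """Protocol sequence: TR 5 ms, TE 2.4 ms, FA 4 degrees."""
    return SequenceParams(tr_ms=5.0, te_ms=2.4, fa_deg=4.0)


@pytest.fixture(scope="session")
def tubes32():
    return make_default_phantom(32, "tubes")


@pytest.fixture(scope="session")
def brain32():
    return make_default_phantom(32, "brain_slice")


@pytest.fixture(scope="session")
def reg_image(seq):
    """Smooth brain-like image with air background, for registration tests."""
    ph = make_default_phantom(64, "brain_slice")
    return ndimage.gaussian_filter(baseline_image(ph, seq), 1.0)
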