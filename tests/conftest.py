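import numpy as np
import pytest

from redoxlan import FourPL, default_truth, reference_calibration


@pytest.fixture
def paper_calibration():
    """The packaged luminescence calibration (percent convention)."""
    return reference_calibration()


@pytest.fixture
def router_truth():
    """A representative 4PL truth for the bare reducer culture."""
    return FourPL(A=0.05, B=1.6, C=30.0, D=2.5)


@pytest.fixture
def lan_truth():
    return default_truth()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
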