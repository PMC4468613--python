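import numpy as np
import pytest

from hrfit.hrf import Paradigm


@pytest.fixture(scope="session")
def paradigm() -> Paradigm:
    """The default 10/10/30 s block at 1.81 Hz (90 samples over ~50 s)."""
    return Paradigm()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
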