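import numpy as np
import pytest

from csarray import datasets


@pytest.fixture(scope="session")
def fingerprints():
    return datasets.default_fingerprints()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
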