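import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pbrefine.pb_align import default_matrix
from pbrefine.pb_alphabet import load_alphabet


@pytest.fixture(scope="session")
def alphabet():
    return load_alphabet()


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
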