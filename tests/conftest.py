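import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ramphylo import parse_newick  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quartet():
    """Balanced 4-leaf tree ((A,B),(C,D))."""
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def caterpillar():
    return parse_newick("((((A,B),C),D),E);")


@pytest.fixture
def star6():
    return parse_newick("(A,B,C,D,E,F);")
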