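import sys
from pathlib import Path

import numpy as np
import pytest

# make the naive oracle importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_series(rng, m, scale=10.0, offset=0.0):
    """A random non-degenerate (non-constant actual) paired series."""
    while True:
        actual = offset + scale * rng.standard_normal(m)
        predicted = offset + scale * rng.standard_normal(m)
        if m == 1 or np.ptp(actual) > 1e-9:
            return actual, predicted
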