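import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from helpers import make_table  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_blob_table(rng):
    """Two well-separated Gaussian blobs (sigma 21 nm, 50 points each), one mark."""
    mean_a, mean_b = np.array([0.0, 0.0]), np.array([300.0, 0.0])
    pts = np.vstack(
        [mean_a + rng.normal(0, 21.0, (50, 2)), mean_b + rng.normal(0, 21.0, (50, 2))]
    )
    return make_table(pts, "histone"), (mean_a, mean_b)
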