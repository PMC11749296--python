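import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pbhforecast.cgm_data import MISSING, OBSERVED, CGMTrace


def make_trace(values, status=None, subject_id="test", t0=0.0) -> CGMTrace:
    """Build a gridded trace from a value list; NaN entries become missing."""
    vals = np.asarray(values, dtype=float)
    if status is None:
        status = np.where(np.isnan(vals), MISSING, OBSERVED).astype(np.uint8)
    return CGMTrace(subject_id=subject_id, t0=t0, values=vals, status=status)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def glucose_series(rng):
    """A plausible stationary CGM-like series for estimator tests."""
    n = 500
    e = rng.normal(0, 5, n)
    y = np.empty(n)
    y[0] = 120.0
    for i in range(1, n):
        y[i] = 100 + 0.9 * (y[i - 1] - 100) + e[i]
    return np.clip(y, 40, 400)
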