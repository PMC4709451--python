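import numpy as np
import pandas as pd
import pytest

from synapse_smlm.simulate import TABLE_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(x, y, intensity=None, channel=1, frame=0):
    """Minimal well-formed localization table for unit tests."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = len(x)
    if intensity is None:
        intensity = np.ones(n)
    return pd.DataFrame(
        {
            "frame": np.broadcast_to(frame, n).copy(),
            "x_nm": x,
            "y_nm": y,
            "intensity": np.broadcast_to(np.asarray(intensity, dtype=float), n).copy(),
            "width_nm": np.full(n, 150.0),
            "asymmetry": np.ones(n),
            "channel": np.broadcast_to(channel, n).copy(),
        }
    )[TABLE_COLUMNS]


@pytest.fixture
def table_factory():
    return make_table
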