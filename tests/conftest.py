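import numpy as np
import pytest

import toolgaze as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def config():
    return tg.RunConfig(cylinder_physical_length_mm=150.0)


@pytest.fixture(scope="session")
def default_params():
    return tg.LearningParams()


@pytest.fixture(scope="session")
def one_subject(default_params):
    """One fully materialized subject (8 sessions, gaze in sessions 1 and 8)."""
    return tg.simulate_subject(default_params, "S01", 20240901)


def make_stream(points, start_idx: int = 0, valid=None, trial_id="t"):
    """Gaze stream from a point list on the 30 Hz sample grid."""
    n = len(points)
    t = np.array([((start_idx + i) * 1000) // 30 for i in range(n)], dtype=np.int64)
    pts = np.asarray(points, dtype=float)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return tg.GazeStream(
        t=t, x=pts[:, 0], y=pts[:, 1], valid=np.asarray(valid, dtype=bool),
        trial_id=trial_id,
    )
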