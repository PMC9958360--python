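import numpy as np
import pytest

from imsync import LandmarkSeries, SyntheticConfig
from imsync.landmarks import LANDMARK_NAMES


@pytest.fixture
def rng():
    return np.random.default_rng(1)


def make_series(coords, confidence=None, frame_rate=30.0):
    """Build a LandmarkSeries from a (frames, 67, 2) array."""
    coords = np.asarray(coords, dtype=float)
    if confidence is None:
        confidence = np.full(coords.shape[:2], 0.9)
    return LandmarkSeries(participant_id="p1", trial_id="t1",
                          frame_rate=frame_rate, coords=coords,
                          confidence=confidence)


@pytest.fixture
def constant_series():
    coords = np.tile(np.linspace(10, 500, len(LANDMARK_NAMES))[None, :, None],
                     (5, 1, 2))
    return make_series(coords)


@pytest.fixture
def random_series(rng):
    n, m = 120, len(LANDMARK_NAMES)
    coords = 300 + 5 * rng.standard_normal((n, m, 2))
    conf = rng.uniform(0.3, 1.0, (n, m))
    return make_series(coords, conf)


@pytest.fixture(scope="session")
def tiny_study():
    """A small coupled study for integration-level tests."""
    from imsync.synthetic import generate_study, homologous_response_matrix
    cfg = SyntheticConfig(
        n_dyads=6, duration=40.0, seed=11, missing_frac=0.0, outlier_frac=0.0,
        cross_part_matrix=tuple(map(tuple, homologous_response_matrix())))
    return generate_study(cfg, level="velocity"), cfg
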