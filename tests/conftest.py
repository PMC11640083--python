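import numpy as np
import pytest

from seigait.pose import JointId
from seigait.synthetic import GaitParams, generate_gait_sequence


def standing_keypoints(conf=0.9, dx=0.0, dy=0.0):
    """12 body joints of a plausible standing figure, as raw tuples."""
    coords = {
        JointId.RIGHT_SHOULDER: (185, 140),
        JointId.LEFT_SHOULDER: (215, 140),
        JointId.RIGHT_ELBOW: (180, 185),
        JointId.LEFT_ELBOW: (220, 185),
        JointId.RIGHT_WRIST: (178, 225),
        JointId.LEFT_WRIST: (222, 225),
        JointId.RIGHT_HIP: (190, 230),
        JointId.LEFT_HIP: (210, 230),
        JointId.RIGHT_KNEE: (188, 300),
        JointId.LEFT_KNEE: (212, 300),
        JointId.RIGHT_FOOT: (186, 370),
        JointId.LEFT_FOOT: (214, 370),
    }
    return [(j, x + dx, y + dy, conf) for j, (x, y) in coords.items()]


@pytest.fixture
def raw_body_keypoints():
    return standing_keypoints()


@pytest.fixture(scope="session")
def walking_sequence():
    """A clean 40-frame synthetic walk (no jitter) shared across tests."""
    params = GaitParams(tremor_jitter=0.0, seed=7)
    return generate_gait_sequence(params, 40)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
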