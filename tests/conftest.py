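import numpy as np
import pytest

import handkin as hk


@pytest.fixture(scope="session")
def skeleton():
    return hk.build_default_skeleton()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def make_angle_traj(angles, fps=30.0, joints=None):
    """Build an AngleTrajectory from an (n_frames, n_joints) array."""
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    if joints is None:
        joints = hk.ANGLE_LABELS[:angles.shape[1]]
    return hk.AngleTrajectory(angles, fps=fps, joints=tuple(joints))


def single_joint_traj(series, fps=30.0, joint=("middle", "mcp")):
    return make_angle_traj(np.asarray(series, dtype=float)[:, None],
                           fps=fps, joints=(joint,))
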