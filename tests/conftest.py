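import numpy as np
import pytest

from rewardrs.design import TaskConfig, generate_session_design
from rewardrs.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def small_task_cfg():
    """Short run: 20 trials in 200 volumes at TR 1 s."""
    return TaskConfig(n_volumes=200, n_trials=20)


@pytest.fixture(scope="session")
def small_design(small_task_cfg):
    return generate_session_design("neutral", seed=3, cfg=small_task_cfg)


@pytest.fixture(scope="session")
def cube_phantom():
    """One 5x5x5 cubic ROI inside a 12^3 grid."""
    vox = np.argwhere(np.ones((5, 5, 5), dtype=bool)) + 2
    return build_phantom(PhantomSpec((12, 12, 12), {"NAcc": vox}))


@pytest.fixture(scope="session")
def two_roi_phantom():
    a = np.argwhere(np.ones((4, 4, 4), dtype=bool)) + 1
    b = np.argwhere(np.ones((3, 3, 3), dtype=bool)) + np.array([8, 8, 8])
    return build_phantom(PhantomSpec((14, 14, 14), {"NAcc": a, "mOFC": b}))
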