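import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gazemux.model import VideoMeta
from gazemux.synthetic import GazeGenSpec, gen_gaze


@pytest.fixture
def video():
    return VideoMeta(640, 480, 25.0)


@pytest.fixture
def small_video():
    return VideoMeta(320, 240, 25.0)


@pytest.fixture
def trajectory(video):
    """A deterministic synthetic trajectory with pupil data."""
    traj, _ = gen_gaze(GazeGenSpec(seed=7, video=video))
    return traj
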