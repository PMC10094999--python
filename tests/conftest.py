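import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from calmdx.io_formats import SensorVideo, SessionMeta


def make_video(frames: np.ndarray, rate_hz: float = 10.0, stim_time_s: float = 0.0,
               group: str = "formalin", session_id: str = "t") -> SensorVideo:
    """SensorVideo around a raw frame stack, t=0 at stim_time_s."""
    frames = np.asarray(frames)
    time_s = np.arange(frames.shape[0]) / rate_hz - stim_time_s
    meta = SessionMeta(session_id=session_id, frame_rate_hz=rate_hz,
                       stim_time_s=stim_time_s, group=group)
    return SensorVideo(frames=frames, time_s=time_s, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def constant_video():
    """3-min 10 Hz constant video (value 100), stim at 90 s."""
    frames = np.full((1800, 8, 6), 100, dtype=np.uint16)
    return make_video(frames, rate_hz=10.0, stim_time_s=90.0)
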