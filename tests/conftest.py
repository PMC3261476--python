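import numpy as np
import pytest

import pulsecam as pc


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def make_stream(rng, width=8, height=6, fps=20.0, n_frames=5):
    """Random small nv21 stream for I/O and extraction tests."""
    meta = pc.VideoMeta(width=width, height=height, fps=fps, n_frames=n_frames)
    y = rng.integers(0, 256, size=(n_frames, height, width), dtype=np.uint8)
    vu = rng.integers(0, 256, size=(n_frames, height // 2, width), dtype=np.uint8)
    return pc.FrameStream(meta, y, vu)


def uniform_frame(value, width=8, height=6, vu_value=128):
    y = np.full((height, width), value, dtype=np.uint8)
    vu = np.full((height // 2, width), vu_value, dtype=np.uint8)
    return pc.Frame(y, vu)


@pytest.fixture(scope="session")
def scaled_study():
    """One simulated validation study, scaled to 4 subjects for test runtime.

    3 conditions x 5 minutes each, full-rate 20 fps QCIF rendering through
    the real extraction and detection pipeline; shared across the
    study-level tests.
    """
    cfg = pc.StudyConfig(n_subjects=4, seed=1234)
    return pc.simulate_study(cfg)
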