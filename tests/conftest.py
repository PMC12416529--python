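import numpy as np
import pytest

from antpupil import io_eyelink, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_session(n=3000, seed=0, blinks=(), saccades=(), messages=()):
    """Small synthetic EyeSession on the 2 ms grid."""
    r = np.random.default_rng(seed)
    times = np.arange(n) * 2.0
    pupil = np.round(3000.0 + 5.0 * np.sin(times / 500.0) + r.normal(0, 0.5, n), 2)
    gaze = np.column_stack([
        np.round(960 + r.normal(0, 5, n), 1),
        np.round(540 + r.normal(0, 5, n), 1),
    ])
    return io_eyelink.EyeSession(
        sample_times=times, pupil=pupil, gaze=gaze,
        blinks=list(blinks), saccades=list(saccades), messages=list(messages),
    )


@pytest.fixture
def small_session():
    return make_session()


@pytest.fixture
def subject_params():
    """A deterministic control-cohort subject draw."""
    cfg = simulate.default_config(master_seed=7)
    r = np.random.default_rng(42)
    return simulate.draw_subject_params(cfg.control, r, "control-test", seed=1234)
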