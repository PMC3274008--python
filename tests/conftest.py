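import numpy as np
import pytest

from emgfatigue.preprocessing import WindowSpec
from emgfatigue.synthetic import RMSProfile, StageTimeline, SyntheticTrialConfig


@pytest.fixture
def short_timeline():
    return StageTimeline(t_transition_onset=20.0, t_fatigue_onset=45.0, t_end=60.0)


@pytest.fixture
def short_cfg(short_timeline):
    """Small fatiguing trial: fast enough for unit tests, long enough for
    every stage to appear."""
    return SyntheticTrialConfig(duration=60.0, timeline=short_timeline, seed=7)


@pytest.fixture
def flat_cfg(short_timeline):
    """Stationary control: constant median frequency and RMS."""
    return SyntheticTrialConfig(
        duration=60.0,
        timeline=short_timeline,
        mf_start=100.0,
        mf_end=100.0,
        rms_profile=RMSProfile(1.0, 1.0, 1.0),
        seed=11,
    )


@pytest.fixture
def one_second_windows():
    return WindowSpec(1.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
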