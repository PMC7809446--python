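import pytest

from acp import gradient


@pytest.fixture(scope="session")
def grad() -> gradient.GradientSpec:
    return gradient.GradientSpec()


@pytest.fixture(scope="session")
def cal() -> gradient.Calibration:
    return gradient.default_calibration()


@pytest.fixture()
def small_pool():
    """A tiny mixture: one active species at 6.5 S plus three decoys."""
    return [
        gradient.Species("scr", mass=103.0, s_value=6.5, abundance=1.0,
                         is_active=True),
        gradient.Species("early", mass=40.0, abundance=2.0),
        gradient.Species("mid", mass=120.0, abundance=0.5),
        gradient.Species("late", mass=280.0, abundance=1.5),
    ]
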