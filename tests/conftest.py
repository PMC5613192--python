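import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def recording():
    """Small 3-channel, 60 s, 100 Hz recording with distinct content."""
    from somnevent import Recording

    r = np.random.default_rng(42)
    t = np.arange(6000) / 100.0
    data = np.vstack(
        [
            30.0 * np.sin(2 * np.pi * 1.0 * t) + r.standard_normal(6000),
            10.0 * np.sin(2 * np.pi * 13.0 * t) + r.standard_normal(6000),
            r.standard_normal(6000) * 5.0,
        ]
    )
    return Recording(data, 100.0, ("C3", "Cz", "EMG1"))


@pytest.fixture
def toy_hypnogram():
    """75-minute toy night: 10 Wake / 30 N2 / 20 N3 / 10 REM / 5 Wake."""
    from somnevent import Hypnogram

    codes = (
        [0] * 600 + [2] * 1800 + [3] * 1200 + [4] * 600 + [0] * 300
    )
    return Hypnogram(codes)
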