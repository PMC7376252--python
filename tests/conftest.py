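import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhythmkit.studies import two_condition_study

settings.register_profile(
    "rhythmkit",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("rhythmkit")

ZT = (3.0, 9.0, 15.0, 21.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


@pytest.fixture
def noisy_16pt():
    """Frozen 16-point series from a known rhythmic model plus noise."""
    r = np.random.default_rng(7)
    t = np.repeat(ZT, 4)
    y = 5.0 + 2.0 * np.cos(2 * np.pi * (t - 8.0) / 24.0) + r.normal(0, 1.0, t.size)
    return t, y


def two_condition_config(phi_b=17.0, noise=1.0, seed=0, reps=(3, 6)):
    """Control/challenge study for one feature at the around-the-clock design."""
    return two_condition_study(phi_b=phi_b, noise=noise, seed=seed, reps=reps)
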