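import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vertds as v

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibrated synthetic cohort at the study's sample sizes."""
    return v.make_synthetic_cohort(v.CohortSimSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ellipse_points(a, b, phi=0.0, n=360, center=(0.0, 0.0), t0=0.0, t1=2 * np.pi,
                   endpoint=False):
    """Uniform-in-parameter sample of an (arc of an) ellipse."""
    t = np.linspace(t0, t1, n, endpoint=endpoint)
    x, y = a * np.cos(t), b * np.sin(t)
    c, s = np.cos(phi), np.sin(phi)
    return np.column_stack([c * x - s * y + center[0], s * x + c * y + center[1]])
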