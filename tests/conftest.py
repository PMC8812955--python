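import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220203)


@pytest.fixture
def het_sample():
    """A visibly heterogeneous 6-study sample (Q = 12.72 on 5 df)."""
    from hetsim.meta import MetaSample
    return MetaSample([0.05, 0.62, -0.22, 0.95, 0.30, 0.48],
                      [0.030, 0.080, 0.050, 0.110, 0.045, 0.070])
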