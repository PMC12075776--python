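import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exact_doubling_curve():
    """Noise-free exponential curve: one doubling per day from 1000 cells/ml."""
    from ecophys.growth import GrowthCurve

    times = np.arange(7.0)
    return GrowthCurve(
        strain_id="US3C007-like",
        replicate_id="r1",
        condition={"temperature_C": 18.5},
        times=times,
        densities=1000.0 * 2.0**times,
    )
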