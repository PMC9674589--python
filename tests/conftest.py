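import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from treesel.demography import Demography

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def const_dem() -> Demography:
    """Constant diploid N = 1000 (2000 haploid copies)."""
    return Demography.constant(1000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def flat_trajectory(x: float, length: int, dem: Demography, absorbed: bool = True):
    """Trajectory clamped at x for ``length`` generations, optionally ending
    at the origin (frequency 0)."""
    from treesel.simulate import Trajectory

    freqs = np.full(length, x)
    if absorbed:
        freqs = np.concatenate([freqs, [0.0]])
    return Trajectory(freqs=freqs, s_true=0.0, demography=dem)
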