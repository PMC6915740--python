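import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from cryoevb.evb import make_windows
from cryoevb.sampling import run_replicate
from cryoevb.surrogate import build_variant

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def spe_system():
    """Psychrophilic-like wildtype preset (low dH, strongly negative TdS)."""
    return build_variant("SPE_like")


@pytest.fixture(scope="session")
def ppe_system():
    """Mesophilic-like wildtype preset (high dH, near-zero TdS)."""
    return build_variant("PPE_like")


@pytest.fixture(scope="session")
def spe_bare(spe_system):
    """SPE-like diabats with the bath removed (purely enthalpic barrier)."""
    return dataclasses.replace(spe_system, bath=())


@pytest.fixture(scope="session")
def small_rep(spe_bare):
    """A quick replicate: 21 windows, 4000 steps each, bath-free."""
    return run_replicate(spe_bare, 295.15, make_windows(21), 4000, replicate_seed=101)


@pytest.fixture(scope="session")
def converged_rep(spe_bare):
    """A well-sampled replicate: 51 windows, 2e4 steps each, bath-free."""
    return run_replicate(spe_bare, 295.15, make_windows(51), 20_000, replicate_seed=77)
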