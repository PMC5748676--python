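import pytest

from snordcluster import (
    RunConfig,
    human_like_params,
    mouse_like_params,
    rabbit_like_params,
    simulate_locus,
)
from snordcluster.msa import DEFAULT_SCORING


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def scoring():
    return DEFAULT_SCORING


@pytest.fixture(scope="session")
def human_sim():
    """Human-shaped synthetic locus: 30 copies, planted groups 9/15/6."""
    return simulate_locus(human_like_params(seed=1))


@pytest.fixture(scope="session")
def mouse_sim():
    """Mouse-shaped synthetic locus: 17 nearly identical copies, minus strand."""
    return simulate_locus(mouse_like_params(seed=3))


@pytest.fixture(scope="session")
def rabbit_sim():
    """Rabbit-shaped synthetic locus: two groups plus two planted outliers."""
    return simulate_locus(rabbit_like_params(seed=5))
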