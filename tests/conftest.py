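import numpy as np
import pytest

from latentord import (
    CommunityMatrix,
    MCMCSettings,
    ModelSpec,
    SimulationDesign,
    fit,
    generate_community,
)


@pytest.fixture(scope="session")
def binary_fit():
    """A small fitted presence/absence model reused across summary tests."""
    design = SimulationDesign(family="binary", n=15, p=15, seed=42)
    Y, truth = generate_community(design, 0)
    chains = fit(
        Y,
        ModelSpec(family="binary"),
        MCMCSettings(n_iter=2000, burn_in=1000, thin=2, seed=7),
    )
    return Y, truth, chains


@pytest.fixture(scope="session")
def count_fit():
    """A small fitted Poisson model."""
    design = SimulationDesign(family="poisson", n=15, p=15, seed=43)
    Y, truth = generate_community(design, 0)
    chains = fit(
        Y,
        ModelSpec(family="poisson"),
        MCMCSettings(n_iter=2500, burn_in=1200, thin=2, seed=8),
    )
    return Y, truth, chains


@pytest.fixture(scope="session")
def ordinal_fit():
    """A small fitted cumulative-probit model with K=5 classes."""
    design = SimulationDesign(family="ordinal", n=15, p=15, K=5, seed=44)
    Y, truth = generate_community(design, 0)
    chains = fit(
        Y,
        ModelSpec(family="ordinal", n_levels=5),
        MCMCSettings(n_iter=2000, burn_in=1000, thin=2, seed=9),
    )
    return Y, truth, chains


@pytest.fixture
def toy_binary_matrix():
    return CommunityMatrix(np.array([[1, 0], [0, 1]]), family="binary")
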