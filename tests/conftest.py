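"""Shared fixtures: small networks and short simulations."""

import numpy as np
import pytest

from mgc import (
    NetworkSpec,
    SimulationConfig,
    build_network,
    make_pulse,
    simulate,
)


@pytest.fixture(scope="session")
def fpa_net():
    return build_network(NetworkSpec(regime="fpa", seed=11))


@pytest.fixture(scope="session")
def lca_net():
    return build_network(NetworkSpec(regime="lca", seed=11))


@pytest.fixture(scope="session")
def fpa_trace(fpa_net):
    """One noisy 700 ms presentation of a balanced blend, FPA."""
    return simulate(
        fpa_net, make_pulse(0.5), SimulationConfig(duration_ms=700.0, seed=5)
    )


@pytest.fixture(scope="session")
def lca_trace(lca_net):
    return simulate(
        lca_net, make_pulse(0.5), SimulationConfig(duration_ms=700.0, seed=5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
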