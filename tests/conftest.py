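import numpy as np
import pytest
from hypothesis import settings

# property tests run derandomized so failures are reproducible
settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from chimeranet import (
    LayeredNetwork,
    add_interlayer_links,
    generate_modular_subnetwork,
    toy_fixture,
)


@pytest.fixture(scope="session")
def two_rings():
    return toy_fixture("two_rings", size=6)


@pytest.fixture(scope="session")
def two_cliques():
    return toy_fixture("two_cliques", size=4)


@pytest.fixture(scope="session")
def clustered_pair():
    """Two rewired N=200, <k>=10, C=0.7 subnetworks (expensive; built once)."""
    adj_a = generate_modular_subnetwork(200, 10, 0.7, seed=42)
    adj_b = generate_modular_subnetwork(200, 10, 0.7, seed=43)
    return adj_a, adj_b


@pytest.fixture(scope="session")
def modular_net(clustered_pair):
    """The standard synthetic two-layer network with 100 inter-links."""
    adj_a, adj_b = clustered_pair
    return add_interlayer_links(adj_a, adj_b, 100, seed=7)


@pytest.fixture(scope="session")
def single_node_net():
    """One isolated node per layer, no links at all (pure FHN dynamics)."""
    z = np.zeros((1, 1), dtype=np.int8)
    return LayeredNetwork(z, z.copy(), z.copy())
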