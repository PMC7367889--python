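import numpy as np
import pytest

from edith.network import Reach, RiverNetwork, assign_hydraulics, strahler_orders
from edith.synthetic import synthetic_covariates, synthetic_network


def build_network(rows):
    """Construct a RiverNetwork from (id, downstream, length, area) tuples."""
    net = RiverNetwork(
        [Reach(id=i, downstream_id=d, length=L, area_km2=A)
         for i, d, L, A in rows]
    )
    strahler_orders(net)
    return net


@pytest.fixture
def y_network():
    """Two headwaters joining a stem, with hydraulics from the default laws."""
    net = build_network(
        [
            ("a", "c", 1000.0, 1.0),
            ("b", "c", 800.0, 2.0),
            ("c", None, 1200.0, 3.5),
        ]
    )
    return assign_hydraulics(net)


@pytest.fixture
def random_tree():
    """Seeded 50-reach synthetic network with hydraulics assigned."""
    return synthetic_network(50, seed=11)


@pytest.fixture
def random_tree_covariates(random_tree):
    return synthetic_covariates(random_tree, 4, seed=12)
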