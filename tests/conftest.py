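import pandas as pd
import pytest

from hydroconn import (
    Link,
    PassabilityPolicy,
    Reach,
    RiverNetwork,
    RiverscapeConfig,
    generate_network,
    place_barriers,
    six_reach_fixture,
    toy_fixture,
)


@pytest.fixture
def toy():
    """Two equal reaches, one dam: RCI (0.70, 0.55), CCI 0.625, dCCI 60%."""
    return toy_fixture()


@pytest.fixture
def six_reach():
    return six_reach_fixture()


@pytest.fixture
def sisters():
    """Outlet with two sister tributaries: a waterfall on one, a dam on the other."""
    net = RiverNetwork(
        [
            Reach("out", 2.0, "C0", None),
            Reach("left", 1.0, "C0", "out"),
            Reach("right", 1.0, "C0", "out"),
        ],
        [
            Link(link_id="wf", kind="waterfall", upstream_reach="left", downstream_reach="out"),
            Link(link_id="dam", kind="anthropogenic", upstream_reach="right", downstream_reach="out"),
        ],
    )
    return net, PassabilityPolicy()


def random_riverscape(seed: int, n_reaches: int = 20, n_waterfalls: int = 1,
                      n_dams: int = 3, n_planned: int = 0):
    """Small seeded riverscape with mixed barriers, for oracle comparisons."""
    cfg = RiverscapeConfig(
        n_reaches=n_reaches,
        n_waterfalls=n_waterfalls,
        n_dams_existing=n_dams,
        n_dams_planned=n_planned,
        seed=seed,
    )
    return place_barriers(generate_network(cfg), cfg), PassabilityPolicy()


def uniform_suit(network, value: float = 1.0) -> pd.Series:
    return pd.Series(value, index=network.reach_ids)
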