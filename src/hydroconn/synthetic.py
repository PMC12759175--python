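"""Seeded generators for dendritic riverscapes, barrier portfolios and
suitability layers.

The generator emulates the statistical structure of a large tropical basin at
desk scale: a dendritic tree of reaches with log-normal lengths, a mixed
portfolio of natural waterfalls and existing/planned dams (optionally biased
toward the mainstem), and per-species habitat suitability that is spatially
autocorrelated along the network and declines monotonically through future
epochs, faster under the pessimistic climate scenario. Everything is
bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .connectivity import PassabilityPolicy
from .river_graph import Link, NetworkError, Reach, RiverNetwork, split_reach_at_barrier
from .suitability import SuitabilitySet, group_mean

__all__ = [
    "RiverscapeConfig",
    "generate_network",
    "place_barriers",
    "generate_suitability",
    "generate_riverscape",
    "toy_fixture",
    "six_reach_fixture",
]

EPOCH_INDEX = {"current": 0, "2030": 1, "2050": 2, "2070": 3, "2090": 4}


@dataclass(frozen=True)
class RiverscapeConfig:
    """Knobs of the synthetic riverscape.

    ``length_distribution`` is (mean, sd) of log length in km. ``trend`` is
    the per-epoch-step downward drift of the latent suitability field per
    climate scenario (pessimistic > moderate, so suitable habitat contracts
    faster under stronger forcing). Group sizes default to the 27 migratory +
    25 sedentary frugivore assemblage the analysis targets.
    """

    n_reaches: int = 500
    branching_prob: float = 0.35
    length_distribution: tuple[float, float] = (1.5, 0.6)
    n_waterfalls: int = 5
    n_dams_existing: int = 30
    n_dams_planned: int = 25
    placement: str = "uniform"
    super_barrier: bool = False
    suitability_autocorrelation: float = 0.8
    trend: dict = field(
        default_factory=lambda: {"moderate": 0.2, "pessimistic": 0.45}
    )
    n_migratory: int = 27
    n_sedentary: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reaches < 1:
            raise ValueError("n_reaches must be >= 1")
        if not 0.0 < self.branching_prob < 1.0:
            raise ValueError("branching_prob must lie in (0, 1)")
        if not 0.0 <= self.suitability_autocorrelation < 1.0:
            raise ValueError("suitability_autocorrelation must lie in [0, 1)")
        if self.placement not in ("uniform", "mainstem_biased"):
            raise ValueError(f"unknown placement {self.placement!r}")
        for k in ("n_waterfalls", "n_dams_existing", "n_dams_planned"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")

    def _rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "network": np.random.default_rng(children[0]),
            "barriers": np.random.default_rng(children[1]),
            "suitability": np.random.default_rng(children[2]),
        }


def generate_network(config: RiverscapeConfig) -> RiverNetwork:
    """Grow a random dendritic tree from the outlet.

    Each step either extends a current headwater tip or, with probability
    ``branching_prob``, starts a new branch off a reach that has exactly one
    upstream neighbour (confluences are binary). Lengths are log-normal.
    """
    rng = config._rngs()["network"]
    n = config.n_reaches
    width = max(len(str(n - 1)), 1)
    ids = [f"r{k:0{width}d}" for k in range(n)]
    parent: dict[str, Optional[str]] = {ids[0]: None}
    n_children = {ids[0]: 0}
    for k in range(1, n):
        tips = [v for v, c in n_children.items() if c == 0]
        branchable = [v for v, c in n_children.items() if c == 1]
        if branchable and (not tips or rng.random() < config.branching_prob):
            par = branchable[rng.integers(len(branchable))]
        else:
            par = tips[rng.integers(len(tips))]
        parent[ids[k]] = par
        n_children[par] += 1
        n_children[ids[k]] = 0
    mu, sd = config.length_distribution
    lengths = np.exp(rng.normal(mu, sd, size=n))
    reaches = [
        Reach(
            reach_id=ids[k],
            length_km=float(lengths[k]),
            catchment_id="C0",
            downstream_reach_id=parent[ids[k]],
        )
        for k in range(n)
    ]
    links = [
        Link(
            link_id=f"conf_{rid}",
            kind="confluence",
            upstream_reach=rid,
            downstream_reach=parent[rid],
        )
        for rid in ids
        if parent[rid] is not None
    ]
    return RiverNetwork(reaches, links)


def _subtree_lengths(network: RiverNetwork) -> dict[str, float]:
    """Total river length in the subtree rooted at each reach (itself included)."""
    g = network.graph
    root = network.outlet()
    order, parent = [root], {root: None}
    stack = [root]
    while stack:
        v = stack.pop()
        for nb in g.neighbors(v):
            if nb != parent[v]:
                parent[nb] = v
                order.append(nb)
                stack.append(nb)
    sub = {v: network.reach(v).length_km for v in order}
    for v in reversed(order[1:]):
        sub[parent[v]] += sub[v]
    return sub


def mainstem(network: RiverNetwork) -> list[str]:
    """Outlet-to-headwater path following the largest subtree at each fork."""
    sub = _subtree_lengths(network)
    path = [network.outlet()]
    while True:
        ups = network.upstream_neighbors(path[-1])
        if not ups:
            return path
        path.append(max(ups, key=lambda v: (sub[v], v)))


def place_barriers(
    network: RiverNetwork, config: RiverscapeConfig
) -> RiverNetwork:
    """Insert the configured barrier portfolio into a barrier-free network.

    Waterfalls and dams are placed in the interiors of distinct randomly
    chosen reaches (splitting each reach at a uniform fraction);
    ``mainstem_biased`` placement up-weights reaches on the mainstem tenfold.
    With ``super_barrier`` an impassable dam (passability 0 both ways) is
    first planted on the confluence that splits the network's total length
    most evenly — the cut that fragments the basin the most.
    """
    rng = config._rngs()["barriers"]
    net = network
    if config.super_barrier:
        if len(net) < 2:
            raise NetworkError("super barrier needs at least 2 reaches")
        sub = _subtree_lengths(net)
        total = net.total_length_km()
        best = max(
            (v for v in net.reach_ids if net.reach(v).downstream_reach_id),
            key=lambda v: (sub[v] * (total - sub[v]), v),
        )
        net = net.add_barrier(
            Link(
                link_id="super_dam",
                kind="anthropogenic",
                status="existing",
                upstream_reach=best,
                downstream_reach=net.reach(best).downstream_reach_id,
                pass_up=0.0,  # the planted barrier blocks passage entirely
                pass_down=0.0,
            )
        )
    specs = (
        [("wf", "waterfall", "existing")] * config.n_waterfalls
        + [("dam", "anthropogenic", "existing")] * config.n_dams_existing
        + [("pln", "anthropogenic", "planned")] * config.n_dams_planned
    )
    if not specs:
        return net
    pool = list(net.reach_ids)
    if len(specs) > len(pool):
        raise NetworkError(
            f"{len(specs)} barriers requested but only {len(pool)} reaches"
        )
    if config.placement == "mainstem_biased":
        stem = set(mainstem(net))
        w = np.array([10.0 if r in stem else 1.0 for r in pool])
    else:
        w = np.ones(len(pool))
    chosen = rng.choice(len(pool), size=len(specs), replace=False, p=w / w.sum())
    fractions = rng.uniform(0.2, 0.8, size=len(specs))
    counters: dict[str, int] = {}
    for m, (pos, (prefix, kind, status)) in enumerate(zip(chosen, specs)):
        k = counters.get(prefix, 0)
        counters[prefix] = k + 1
        net = split_reach_at_barrier(
            net,
            pool[pos],
            float(fractions[m]),
            Link(
                link_id=f"{prefix}{k:03d}",
                kind=kind,
                status=status,
                upstream_reach="",
                downstream_reach="",
            ),
        )
    return net


def generate_suitability(
    network: RiverNetwork,
    config: RiverscapeConfig,
    return_species: bool = False,
):
    """Autocorrelated per-species suitability, averaged into group layers.

    Each species gets a latent Gaussian field propagated outlet-to-headwater
    along the tree with lag-1 correlation ``suitability_autocorrelation``
    plus a species-level offset, squashed through a logistic to [0, 1]. For
    future cells a climate- and epoch-dependent drift is subtracted from the
    latent field before squashing, so every reach declines monotonically and
    the pessimistic scenario declines fastest.
    """
    rng = config._rngs()["suitability"]
    rho = config.suitability_autocorrelation
    ids = network.reach_ids
    index = pd.Index(ids)
    n = len(ids)
    n_sp = config.n_migratory + config.n_sedentary
    species = [f"mig_{k:02d}" for k in range(config.n_migratory)] + [
        f"sed_{k:02d}" for k in range(config.n_sedentary)
    ]
    groups = {
        "migratory": species[: config.n_migratory],
        "sedentary": species[config.n_migratory :],
        "combined": species,
    }

    # latent AR(1) field along the tree, vectorized over species
    g = network.graph
    eps = rng.standard_normal((n_sp, n))
    mu = rng.normal(0.0, 0.6, size=n_sp)
    z = np.empty((n_sp, n))
    col = {rid: k for k, rid in enumerate(ids)}
    innov = np.sqrt(1.0 - rho * rho)
    for cid in network.catchment_ids:
        root = network.outlet(cid)
        z[:, col[root]] = eps[:, col[root]]
        parent = {root: None}
        stack = [root]
        while stack:
            v = stack.pop()
            for nb in g.neighbors(v):
                if nb != parent[v]:
                    parent[nb] = v
                    z[:, col[nb]] = (
                        rho * z[:, col[v]] + innov * eps[:, col[nb]]
                    )
                    stack.append(nb)

    cells = [("current", "current")] + [
        (climate, epoch)
        for climate in sorted(config.trend)
        for epoch in ("2030", "2050", "2070", "2090")
    ]
    layers = SuitabilitySet()
    species_layers: dict[tuple[str, str, str], pd.Series] = {}
    for climate, epoch in cells:
        drift = 0.0
        if climate != "current":
            drift = config.trend[climate] * EPOCH_INDEX[epoch]
        suit = expit(z + mu[:, None] + 0.4 - drift)
        per_species = {
            sp: pd.Series(suit[k], index=index) for k, sp in enumerate(species)
        }
        if return_species:
            for sp, s in per_species.items():
                species_layers[(sp, climate, epoch)] = s
        for gname, members in groups.items():
            layers.add(gname, climate, epoch, group_mean(per_species, members))
    if return_species:
        return layers, species_layers
    return layers


def generate_riverscape(
    config: RiverscapeConfig,
) -> tuple[RiverNetwork, PassabilityPolicy, SuitabilitySet]:
    """Network + barriers + suitability + default policy in one call."""
    net = place_barriers(generate_network(config), config)
    return net, PassabilityPolicy(), generate_suitability(net, config)


def toy_fixture() -> tuple[RiverNetwork, PassabilityPolicy, SuitabilitySet]:
    """Two equal reaches separated by one dam, uniform suitability.

    With the default passabilities (dam: up 0.1, down 0.4) the hand-worked
    indices are RCI = 0.70 upstream, 0.55 downstream, CCI = 0.625, and
    removing the dam gives dCCI = 60.0%.
    """
    net = RiverNetwork(
        [
            Reach("up", 1.0, "C0", "out"),
            Reach("out", 1.0, "C0", None),
        ],
        [
            Link(
                link_id="dam1",
                kind="anthropogenic",
                upstream_reach="up",
                downstream_reach="out",
            )
        ],
    )
    suit = SuitabilitySet()
    suit.add(
        "combined", "current", "current", pd.Series(1.0, index=["up", "out"])
    )
    return net, PassabilityPolicy(), suit


def six_reach_fixture() -> tuple[RiverNetwork, PassabilityPolicy, SuitabilitySet]:
    """Six reaches, two dams and a waterfall on a forked tree."""
    reaches = [
        Reach("r0", 10.0, "C0", None),
        Reach("r1", 5.0, "C0", "r0"),
        Reach("r2", 4.0, "C0", "r1"),
        Reach("r3", 3.0, "C0", "r1"),
        Reach("r4", 2.0, "C0", "r2"),
        Reach("r5", 6.0, "C0", "r3"),
    ]
    links = [
        Link(link_id="c0", kind="confluence", upstream_reach="r1", downstream_reach="r0"),
        Link(link_id="d1", kind="anthropogenic", upstream_reach="r2", downstream_reach="r1"),
        Link(link_id="w1", kind="waterfall", upstream_reach="r3", downstream_reach="r1"),
        Link(link_id="c1", kind="confluence", upstream_reach="r4", downstream_reach="r2"),
        Link(link_id="d2", kind="anthropogenic", upstream_reach="r5", downstream_reach="r3", status="planned"),
    ]
    net = RiverNetwork(reaches, links)
    rng = np.random.default_rng(6)
    suit = SuitabilitySet()
    suit.add(
        "combined",
        "current",
        "current",
        pd.Series(
            np.round(rng.uniform(0.2, 0.9, size=6), 3),
            index=[r.reach_id for r in reaches],
        ),
    )
    return net, PassabilityPolicy(), suit
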