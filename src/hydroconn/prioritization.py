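"""Barrier prioritization by leave-one-out connectivity gain (dCCI).

The contribution of a barrier *m* to basin fragmentation is measured by
recomputing the Catchment Connectivity Index with that single barrier made
fully passable (removal for existing dams, prevention of construction for
planned ones) while every other barrier stays in place::

    dCCI_m = 100 * (CCI_without_m - CCI_with_all) / CCI_with_all

dCCI is 0 when the barrier has no effect and grows without bound as the
barrier approaches total fragmentation of the catchment. Ranking barriers by
dCCI across scenario cells (barrier set x climate x epoch x species group)
and averaging the ranks yields the overall prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import rankdata

from .connectivity import (
    ConnectivityResult,
    PassabilityPolicy,
    active_barrier_ids,
    cci,
    rci,
    rcisuit,
)
from .river_graph import NetworkError, RiverNetwork
from .suitability import SuitabilitySet

__all__ = [
    "ScenarioSpec",
    "BarrierImpact",
    "dcci",
    "rank_barriers",
    "mean_rank",
    "default_scenarios",
    "scenario_grid",
]

BARRIER_SETS = ("baseline", "current", "future")
FUTURE_EPOCHS = ("2030", "2050", "2070", "2090")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario grid.

    ``barrier_set``: baseline (waterfalls only) / current (existing barriers)
    / future (current + planned). ``climate`` and ``epoch`` select the
    suitability layer; ``group`` the species group.
    """

    barrier_set: str = "current"
    climate: str = "current"
    epoch: str = "current"
    group: str = "combined"

    def __post_init__(self) -> None:
        if self.barrier_set not in BARRIER_SETS:
            raise ValueError(f"unknown barrier_set {self.barrier_set!r}")
        if self.climate == "current" and self.epoch != "current":
            raise ValueError("climate=current implies epoch=current")
        if self.climate != "current" and self.epoch == "current":
            raise ValueError(f"climate {self.climate!r} needs a future epoch")

    @property
    def label(self) -> str:
        return f"{self.barrier_set}|{self.climate}|{self.epoch}|{self.group}"


@dataclass
class BarrierImpact:
    """Leave-one-out impact of one barrier in one scenario cell."""

    barrier_id: str
    dcci: float
    rank: float


def dcci(
    network: RiverNetwork,
    policy: PassabilityPolicy,
    suitability: Optional[pd.Series],
    barrier_id: str,
    active: Optional[frozenset[str]] = None,
    weighting: str = "suitability",
) -> float:
    """Percent gain in CCI if ``barrier_id`` were fully passable.

    Evaluated for the catchment containing the barrier, with every other
    active barrier left in place; the network is not modified.
    """
    link = network.link(barrier_id)
    if not link.is_barrier:
        raise NetworkError(f"{barrier_id!r} is a confluence, not a barrier")
    if active is not None and barrier_id not in active:
        raise NetworkError(f"barrier {barrier_id!r} is not in the active set")
    catchment = network.reach(link.upstream_reach).catchment_id
    start = cci(network, policy, suitability, weighting=weighting, active=active)
    removed = cci(
        network,
        policy,
        suitability,
        weighting=weighting,
        active=active,
        removed=frozenset({barrier_id}),
    )
    c0 = float(start.loc[catchment])
    c1 = float(removed.loc[catchment])
    if c0 == 0.0:
        raise ValueError(f"CCI of catchment {catchment!r} is zero")
    return (c1 - c0) / c0 * 100.0


def rank_barriers(
    network: RiverNetwork,
    policy: PassabilityPolicy,
    suitability: Optional[pd.Series],
    candidates: Iterable[str],
    active: Optional[frozenset[str]] = None,
    weighting: str = "suitability",
) -> pd.DataFrame:
    """dCCI and rank for each candidate barrier, most impactful first.

    Ranks are 1 = highest dCCI, with ties receiving the average of the tied
    positions; independent of candidate enumeration order.
    """
    ids = sorted(set(candidates))
    if not ids:
        raise ValueError("empty candidate set")
    start = cci(network, policy, suitability, weighting=weighting, active=active)
    vals = []
    for b in ids:
        link = network.link(b)
        if active is not None and b not in active:
            raise NetworkError(f"barrier {b!r} is not in the active set")
        catchment = network.reach(link.upstream_reach).catchment_id
        removed = cci(
            network, policy, suitability, weighting=weighting,
            active=active, removed=frozenset({b}),
        )
        c0 = float(start.loc[catchment])
        if c0 == 0.0:
            raise ValueError(f"CCI of catchment {catchment!r} is zero")
        vals.append((float(removed.loc[catchment]) - c0) / c0 * 100.0)
    df = pd.DataFrame({"barrier_id": ids, "dCCI": vals})
    df["rank"] = rankdata([-v for v in vals], method="average")
    return df.sort_values(
        ["rank", "barrier_id"], kind="mergesort", ignore_index=True
    )


def mean_rank(rankings: Sequence[pd.DataFrame]) -> pd.Series:
    """Mean of per-cell ranks per barrier, sorted ascending (1 = worst barrier).

    All cells must rank the same candidate set.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    ref = set(rankings[0]["barrier_id"])
    for df in rankings[1:]:
        if set(df["barrier_id"]) != ref:
            raise ValueError("rankings cover inconsistent candidate sets")
    stacked = pd.concat(rankings, ignore_index=True)
    return (
        stacked.groupby("barrier_id")["rank"]
        .mean()
        .round(2)
        .sort_values(kind="mergesort")
        .rename("mean_rank")
    )


def candidate_barriers(
    network: RiverNetwork,
    active: frozenset[str],
    include_waterfalls: bool = False,
) -> list[str]:
    """Default candidate set: active anthropogenic barriers (dams).

    Waterfalls stay in the network as natural fragmentation during every
    evaluation; ``include_waterfalls`` adds them to the ranked candidates.
    """
    out = []
    for lk in network.barriers:
        if lk.link_id not in active:
            continue
        if lk.kind == "anthropogenic" or include_waterfalls:
            out.append(lk.link_id)
    return sorted(out)


def default_scenarios(
    barrier_sets: Sequence[str] = ("current", "future"),
    climates: Sequence[str] = ("current", "moderate", "pessimistic"),
    epochs: Sequence[str] = FUTURE_EPOCHS,
    groups: Sequence[str] = ("combined", "migratory", "sedentary"),
) -> list[ScenarioSpec]:
    """The full scenario grid; current climate pairs only with the current epoch."""
    out = []
    for bs in barrier_sets:
        for climate in climates:
            cell_epochs = ("current",) if climate == "current" else epochs
            for epoch in cell_epochs:
                for group in groups:
                    out.append(ScenarioSpec(bs, climate, epoch, group))
    return out


def scenario_grid(
    network: RiverNetwork,
    policy: PassabilityPolicy,
    suitability: SuitabilitySet,
    specs: Iterable[ScenarioSpec],
    rank: bool = False,
    include_waterfalls: bool = False,
    weighting: str = "suitability",
) -> dict[ScenarioSpec, tuple[ConnectivityResult, Optional[pd.DataFrame]]]:
    """Connectivity indices (and optional barrier ranking) per scenario cell.

    Each cell activates its barrier set, selects the (group, climate, epoch)
    suitability layer, and computes RCI, RCIsuit and CCI; with ``rank=True``
    the leave-one-out ranking over the cell's candidate barriers is added
    (skipped where the cell has no candidates). Deterministic given inputs.
    """
    out: dict[ScenarioSpec, tuple[ConnectivityResult, Optional[pd.DataFrame]]] = {}
    for spec in specs:
        layer = suitability.get(spec.group, spec.climate, spec.epoch)
        active = active_barrier_ids(network, spec.barrier_set)
        r = rci(network, policy, active=active)
        rs = rcisuit(r, layer.reindex(r.index).fillna(0.0))
        c = cci(
            network, policy, layer, weighting=weighting,
            active=active, rci_vector=r,
        )
        result = ConnectivityResult(rci=r, rcisuit=rs, cci=c, scenario=spec)
        ranking = None
        if rank:
            cands = candidate_barriers(network, active, include_waterfalls)
            if cands:
                ranking = rank_barriers(
                    network, policy, layer, cands,
                    active=active, weighting=weighting,
                )
        out[spec] = (result, ranking)
    return out
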