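"""River network as a graph: reaches are nodes, barriers and confluences are edges.

A riverscape is modelled as a forest of dendritic trees. Each reach (a river
segment between two neighbouring confluences or barriers) is a node carrying a
length in km and a catchment id; each edge is either a *confluence* (fully
passable junction) or a *barrier* (waterfall or anthropogenic infrastructure)
with direction-specific passabilities. Flow direction is encoded by the
``downstream_reach_id`` pointer; the single reach per catchment without one is
the outlet.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import networkx as nx
import pandas as pd

__all__ = [
    "Reach",
    "Link",
    "RiverNetwork",
    "NetworkError",
    "build_network",
    "split_reach_at_barrier",
    "path_links",
]

KINDS = ("confluence", "waterfall", "anthropogenic")
STATUSES = ("existing", "planned")


class NetworkError(ValueError):
    """Raised when a reach/barrier table violates the network invariants."""


@dataclass(frozen=True)
class Reach:
    """A river segment between two neighbouring confluences or barriers."""

    reach_id: str
    length_km: float
    catchment_id: str = "C0"
    downstream_reach_id: Optional[str] = None
    geometry: Optional[object] = None  # shapely LineString, decorative

    def __post_init__(self) -> None:
        if not self.length_km > 0:
            raise NetworkError(
                f"reach {self.reach_id!r}: length_km must be > 0, got {self.length_km}"
            )


@dataclass(frozen=True)
class Link:
    """An edge joining two adjacent reaches: a confluence or a barrier.

    ``pass_up``/``pass_down`` are optional per-barrier passability overrides in
    [0, 1]; when unset the :class:`~hydroconn.connectivity.PassabilityPolicy`
    defaults for the link's ``kind`` apply.
    """

    link_id: str
    kind: str
    upstream_reach: str
    downstream_reach: str
    status: str = "existing"
    pass_up: Optional[float] = None
    pass_down: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise NetworkError(f"link {self.link_id!r}: unknown kind {self.kind!r}")
        if self.status not in STATUSES:
            raise NetworkError(f"link {self.link_id!r}: unknown status {self.status!r}")
        for name, v in (("pass_up", self.pass_up), ("pass_down", self.pass_down)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise NetworkError(
                    f"link {self.link_id!r}: {name}={v} outside [0, 1]"
                )
        if self.kind == "confluence" and (
            (self.pass_up not in (None, 1.0)) or (self.pass_down not in (None, 1.0))
        ):
            raise NetworkError(
                f"link {self.link_id!r}: confluences are fully passable"
            )

    @property
    def is_barrier(self) -> bool:
        return self.kind != "confluence"


class RiverNetwork:
    """A forest of reaches joined by confluence and barrier links.

    Thin wrapper around an undirected :class:`networkx.Graph`; node keys are
    reach ids with a ``reach`` attribute, edges carry a ``link`` attribute.
    The object validates the forest invariants on construction and is treated
    as immutable by all analysis code (mutating operations return copies).
    """

    def __init__(self, reaches: Iterable[Reach], links: Iterable[Link]):
        g = nx.Graph()
        for r in reaches:
            if r.reach_id in g:
                raise NetworkError(f"duplicate reach id {r.reach_id!r}")
            g.add_node(r.reach_id, reach=r)
        for lk in links:
            for rid in (lk.upstream_reach, lk.downstream_reach):
                if rid not in g:
                    raise NetworkError(
                        f"link {lk.link_id!r} references unknown reach {rid!r}"
                    )
            if g.has_edge(lk.upstream_reach, lk.downstream_reach):
                raise NetworkError(
                    f"parallel links between {lk.upstream_reach!r} and "
                    f"{lk.downstream_reach!r} (stack barriers via reach splitting)"
                )
            g.add_edge(lk.upstream_reach, lk.downstream_reach, link=lk)
        self._g = g
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def reach_ids(self) -> list[str]:
        return list(self._g.nodes)

    def reach(self, reach_id: str) -> Reach:
        try:
            return self._g.nodes[reach_id]["reach"]
        except KeyError:
            raise NetworkError(f"unknown reach {reach_id!r}") from None

    @property
    def reaches(self) -> list[Reach]:
        return [self._g.nodes[n]["reach"] for n in self._g.nodes]

    @property
    def links(self) -> list[Link]:
        return [d["link"] for _, _, d in self._g.edges(data=True)]

    def link(self, link_id: str) -> Link:
        for lk in self.links:
            if lk.link_id == link_id:
                return lk
        raise NetworkError(f"unknown link {link_id!r}")

    @property
    def barriers(self) -> list[Link]:
        return [lk for lk in self.links if lk.is_barrier]

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def total_length_km(self) -> float:
        return sum(r.length_km for r in self.reaches)

    @property
    def catchment_ids(self) -> list[str]:
        return sorted({r.catchment_id for r in self.reaches})

    def outlet(self, catchment_id: Optional[str] = None) -> str:
        """Reach id of the outlet (the reach with no downstream neighbour)."""
        outs = [
            r.reach_id
            for r in self.reaches
            if r.downstream_reach_id is None
            and (catchment_id is None or r.catchment_id == catchment_id)
        ]
        if len(outs) != 1:
            raise NetworkError(
                f"expected one outlet for catchment {catchment_id!r}, found {len(outs)}"
            )
        return outs[0]

    def upstream_neighbors(self, reach_id: str) -> list[str]:
        return [
            n
            for n in self._g.neighbors(reach_id)
            if self.reach(n).downstream_reach_id == reach_id
        ]

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        g = self._g
        if g.number_of_nodes() == 0:
            raise NetworkError("empty network")
        ncomp = nx.number_connected_components(g)
        if g.number_of_edges() != g.number_of_nodes() - ncomp:
            raise NetworkError("network contains a cycle")
        for comp in nx.connected_components(g):
            catchments = {self.reach(n).catchment_id for n in comp}
            if len(catchments) != 1:
                raise NetworkError(
                    f"component spans multiple catchments: {sorted(catchments)}"
                )
            outlets = [
                n for n in comp if self.reach(n).downstream_reach_id is None
            ]
            if len(outlets) != 1:
                raise NetworkError(
                    f"catchment {catchments.pop()!r} has {len(outlets)} outlets"
                )
        seen_catchments: dict[str, set] = {}
        for comp in nx.connected_components(g):
            cid = self.reach(next(iter(comp))).catchment_id
            if cid in seen_catchments:
                raise NetworkError(f"catchment {cid!r} split across components")
            seen_catchments[cid] = comp
        # downstream pointers must coincide with graph edges
        for r in self.reaches:
            d = r.downstream_reach_id
            if d is not None and not g.has_edge(r.reach_id, d):
                raise NetworkError(
                    f"reach {r.reach_id!r} points downstream to {d!r} with no link"
                )
        seen_links: set[str] = set()
        for lk in self.links:
            if lk.link_id in seen_links:
                raise NetworkError(f"duplicate link id {lk.link_id!r}")
            seen_links.add(lk.link_id)
            if self.reach(lk.upstream_reach).downstream_reach_id != lk.downstream_reach:
                raise NetworkError(
                    f"link {lk.link_id!r} orientation disagrees with downstream "
                    f"pointer of reach {lk.upstream_reach!r}"
                )

    # -- traversal ---------------------------------------------------------

    def path_links(self, i: str, j: str) -> list[tuple[Link, str]]:
        """Links on the unique tree path from reach *i* to reach *j*.

        Returns ``(link, direction)`` pairs in path order, where direction is
        ``"upstream"`` or ``"downstream"`` as the link is traversed travelling
        from *i* toward *j*.
        """
        self.reach(i), self.reach(j)
        if i == j:
            return []
        try:
            nodes = nx.shortest_path(self._g, i, j)
        except nx.NetworkXNoPath:
            raise NetworkError(
                f"reaches {i!r} and {j!r} lie in different catchments"
            ) from None
        out: list[tuple[Link, str]] = []
        for a, b in itertools.pairwise(nodes):
            lk: Link = self._g.edges[a, b]["link"]
            direction = "upstream" if lk.upstream_reach == b else "downstream"
            out.append((lk, direction))
        return out

    # -- editing (copy-on-write) -------------------------------------------

    def with_links(self, links: Iterable[Link]) -> "RiverNetwork":
        """A copy of this network with the link set replaced."""
        return RiverNetwork(self.reaches, links)

    def add_barrier(self, link: Link) -> "RiverNetwork":
        """A copy with one extra barrier replacing the confluence on its edge.

        The edge between ``link.upstream_reach`` and ``link.downstream_reach``
        must currently be a confluence.
        """
        old = self._g.edges[link.upstream_reach, link.downstream_reach]["link"]
        if old.is_barrier:
            raise NetworkError(
                f"edge {old.link_id!r} already carries a barrier; split the reach"
            )
        links = [lk for lk in self.links if lk.link_id != old.link_id]
        links.append(link)
        return self.with_links(links)


def _auto_link_ids(existing: set[str]) -> Iterator[str]:
    for k in itertools.count():
        cand = f"conf_{k}"
        if cand not in existing:
            existing.add(cand)
            yield cand


def build_network(
    reach_table: pd.DataFrame, barrier_table: Optional[pd.DataFrame] = None
) -> RiverNetwork:
    """Assemble a validated :class:`RiverNetwork` from tabular records.

    ``reach_table`` columns: ``reach_id``, ``length_km``, optional
    ``catchment_id`` and ``next_down`` (empty/NaN for the outlet).
    ``barrier_table`` columns: ``barrier_id``, ``kind``, optional ``status``,
    ``pass_up``, ``pass_down``, and either ``up_reach``/``down_reach`` (the
    barrier sits on that confluence edge) or ``reach_id``/``fraction`` (the
    barrier sits in a reach interior, which is split at load time).

    Adjacent reaches with no barrier between them are joined by implicit
    confluence links, so every catchment is one connected tree.
    """
    reaches = []
    ids = set()
    for row in reach_table.itertuples(index=False):
        rid = str(row.reach_id)
        if rid in ids:
            raise NetworkError(f"duplicate reach id {rid!r} in reach table")
        ids.add(rid)
        nd = getattr(row, "next_down", None)
        nd = None if nd is None or pd.isna(nd) or nd == "" else str(nd)
        try:
            length = float(row.length_km)
        except (TypeError, ValueError):
            raise NetworkError(
                f"reach {rid!r}: non-numeric length_km {row.length_km!r}"
            ) from None
        reaches.append(
            Reach(
                reach_id=rid,
                length_km=length,
                catchment_id=str(getattr(row, "catchment_id", "C0")),
                downstream_reach_id=nd,
            )
        )
    for r in reaches:
        if r.downstream_reach_id is not None and r.downstream_reach_id not in ids:
            raise NetworkError(
                f"reach {r.reach_id!r} points to unknown downstream reach "
                f"{r.downstream_reach_id!r}"
            )
    # chase downstream pointers: any revisit before reaching an outlet is a cycle
    down = {r.reach_id: r.downstream_reach_id for r in reaches}
    settled: set[str] = set()
    for start in down:
        path, v = [], start
        while v is not None and v not in settled:
            if v in path:
                raise NetworkError(f"cycle detected through reach {v!r}")
            path.append(v)
            v = down[v]
        settled.update(path)

    edge_links: dict[tuple[str, str], Link] = {}
    interior: list[tuple[str, float, Link]] = []  # (reach_id, fraction, spec)
    if barrier_table is not None and len(barrier_table):
        for idx, row in enumerate(barrier_table.to_dict("records")):
            bid = str(row["barrier_id"])
            kind = str(row["kind"])
            status = str(row.get("status", "existing") or "existing")

            def _p(key):
                v = row.get(key)
                return None if v is None or pd.isna(v) else float(v)

            up_reach = row.get("up_reach")
            if up_reach is not None and not pd.isna(up_reach) and up_reach != "":
                lk = Link(
                    link_id=bid,
                    kind=kind,
                    status=status,
                    upstream_reach=str(up_reach),
                    downstream_reach=str(row["down_reach"]),
                    pass_up=_p("pass_up"),
                    pass_down=_p("pass_down"),
                )
                key = (lk.upstream_reach, lk.downstream_reach)
                if key in edge_links:
                    raise NetworkError(
                        f"row {idx}: two barriers on edge {key}; use reach_id/fraction"
                    )
                edge_links[key] = lk
            else:
                frac = float(row["fraction"])
                lk = Link(
                    link_id=bid,
                    kind=kind,
                    status=status,
                    upstream_reach="",  # filled in by the split
                    downstream_reach="",
                    pass_up=_p("pass_up"),
                    pass_down=_p("pass_down"),
                )
                interior.append((str(row["reach_id"]), frac, lk))

    links: list[Link] = []
    used_ids = {lk.link_id for lk in edge_links.values()} | {
        lk.link_id for _, _, lk in interior
    }
    autoid = _auto_link_ids(used_ids)
    for r in reaches:
        if r.downstream_reach_id is None:
            continue
        key = (r.reach_id, r.downstream_reach_id)
        if key in edge_links:
            links.append(edge_links.pop(key))
        else:
            links.append(
                Link(
                    link_id=next(autoid),
                    kind="confluence",
                    upstream_reach=r.reach_id,
                    downstream_reach=r.downstream_reach_id,
                )
            )
    if edge_links:
        bad = next(iter(edge_links.values()))
        raise NetworkError(
            f"barrier {bad.link_id!r}: reaches {bad.upstream_reach!r} and "
            f"{bad.downstream_reach!r} are not in upstream->downstream adjacency"
        )

    net = RiverNetwork(reaches, links)
    # Interior barriers split their reach. Fractions are measured as the
    # upstream share of the ORIGINAL reach, so several barriers on one reach
    # are applied upstream-first with the remaining fractions renormalized to
    # the shrinking downstream remainder.
    by_reach: dict[str, list[tuple[float, Link]]] = {}
    for rid, frac, spec in interior:
        by_reach.setdefault(rid, []).append((frac, spec))
    for rid in sorted(by_reach):
        cur_id, consumed = rid, 0.0
        for frac, spec in sorted(by_reach[rid], key=lambda t: (t[0], t[1].link_id)):
            local = (frac - consumed) / (1.0 - consumed)
            if local <= 0.0:  # co-located barriers: consecutive links via a sliver
                local = 1e-9
            net = split_reach_at_barrier(net, cur_id, local, spec)
            cur_id = f"{cur_id}.d"
            consumed = consumed + (1.0 - consumed) * local
    return net


def split_reach_at_barrier(
    network: RiverNetwork, reach_id: str, fraction: float, barrier: Link
) -> RiverNetwork:
    """Split a reach at ``fraction`` of its length and insert ``barrier`` there.

    The original reach is replaced by an upstream part of length
    ``fraction * L`` (original id with suffix ``.u``) and a downstream part of
    length ``(1 - fraction) * L`` (suffix ``.d``); total length is conserved
    and neighbouring links are re-attached to the matching half.
    """
    if not 0.0 < fraction < 1.0:
        raise NetworkError(f"fraction must lie in (0, 1), got {fraction}")
    old = network.reach(reach_id)
    up_id, down_id = f"{reach_id}.u", f"{reach_id}.d"
    for nid in (up_id, down_id):
        if nid in network.graph:
            raise NetworkError(f"split id collision: {nid!r}")
    up_part = Reach(
        reach_id=up_id,
        length_km=fraction * old.length_km,
        catchment_id=old.catchment_id,
        downstream_reach_id=down_id,
    )
    down_part = Reach(
        reach_id=down_id,
        length_km=(1.0 - fraction) * old.length_km,
        catchment_id=old.catchment_id,
        downstream_reach_id=old.downstream_reach_id,
    )
    reaches = [up_part, down_part]
    for r in network.reaches:
        if r.reach_id == reach_id:
            continue
        if r.downstream_reach_id == reach_id:
            r = replace(r, downstream_reach_id=up_id)
        reaches.append(r)
    links = [replace(barrier, upstream_reach=up_id, downstream_reach=down_id)]
    for lk in network.links:
        if lk.upstream_reach == reach_id:
            lk = replace(lk, upstream_reach=down_id)
        if lk.downstream_reach == reach_id:
            lk = replace(lk, downstream_reach=up_id)
        links.append(lk)
    return RiverNetwork(reaches, links)


def path_links(network: RiverNetwork, i: str, j: str) -> list[tuple[Link, str]]:
    """Module-level alias for :meth:`RiverNetwork.path_links`."""
    return network.path_links(i, j)
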