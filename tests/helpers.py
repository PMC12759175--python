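"""Independent brute-force oracles used to cross-check the production code.

Everything here deliberately avoids the library's traversal and index
routines: paths are found by plain breadth-first search over the edge list
and RCI is assembled by explicit enumeration of all ordered reach pairs.
"""

from collections import deque

import pandas as pd

from hydroconn import PassabilityPolicy, RiverNetwork


def bfs_path(network: RiverNetwork, i: str, j: str):
    """Node sequence from i to j found by BFS over the raw edge list."""
    adj: dict[str, list[str]] = {r.reach_id: [] for r in network.reaches}
    for lk in network.links:
        adj[lk.upstream_reach].append(lk.downstream_reach)
        adj[lk.downstream_reach].append(lk.upstream_reach)
    prev = {i: None}
    q = deque([i])
    while q:
        v = q.popleft()
        if v == j:
            break
        for nb in adj[v]:
            if nb not in prev:
                prev[nb] = v
                q.append(nb)
    if j not in prev:
        return None
    path = [j]
    while path[-1] != i:
        path.append(prev[path[-1]])
    return path[::-1]


def oracle_passability(
    network: RiverNetwork,
    policy: PassabilityPolicy,
    i: str,
    j: str,
    removed: frozenset = frozenset(),
    active=None,
) -> float:
    """c_ij by walking the BFS path and multiplying direction-matched values."""
    links = {}
    for lk in network.links:
        links[(lk.upstream_reach, lk.downstream_reach)] = lk
    path = bfs_path(network, i, j)
    c = 1.0
    for a, b in zip(path, path[1:]):
        if (b, a) in links:  # b is the upstream end, so a -> b climbs upstream
            lk, direction = links[(b, a)], "upstream"
        else:
            lk, direction = links[(a, b)], "downstream"
        pu, pd_ = policy.resolve(lk, removed=removed, active=active)
        c *= pu if direction == "upstream" else pd_
    return c


def oracle_rci(
    network: RiverNetwork,
    policy: PassabilityPolicy,
    removed: frozenset = frozenset(),
    active=None,
) -> pd.Series:
    """RCI by explicit enumeration over all ordered pairs within a catchment."""
    out = {}
    by_catch: dict[str, list] = {}
    for r in network.reaches:
        by_catch.setdefault(r.catchment_id, []).append(r)
    for members in by_catch.values():
        W = sum(r.length_km for r in members)
        for ri in members:
            s = 0.0
            for rj in members:
                c = oracle_passability(
                    network, policy, ri.reach_id, rj.reach_id,
                    removed=removed, active=active,
                )
                s += c * rj.length_km
            out[ri.reach_id] = s / W
    return pd.Series(out).reindex(network.reach_ids)
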