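"""Shortest-route analysis over a carbocation reaction network.

Step numbering follows the convention of the originating substrate
chemistry: "step 1" is creation of the trans linear cation from the
ionized substrate and "step 2" its trans/cis isomerization, neither of
which the constitutional network resolves.  Route lengths are therefore
reported as (chemical hops from a seed) + 2, so the first cyclization
products sit at step 3.  Allylic resonance edges are free: they are
bookkeeping, not chemical transformations.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import pandas as pd

from .reactions import ReactionEvent, ReactionType

if TYPE_CHECKING:  # pragma: no cover
    from .enumerate import ReactionNetwork

__all__ = ["STEP_OFFSET", "Route", "shortest_route", "all_shortest_steps",
           "skeleton_min_steps"]

#: Offset between chemical hops from the seed and reported step numbers.
STEP_OFFSET = 2


@dataclass
class Route:
    """One shortest seed-to-target path.

    ``step_count`` is hops + 2 (resonance hops are zero-cost); ``events``
    holds the edge taken into each non-seed node of ``node_keys``.
    """

    node_keys: list[str]
    events: list[ReactionEvent]
    step_count: int


def _edge_cost(ev: ReactionEvent) -> int:
    return 0 if ev.rtype is ReactionType.RESONANCE else 1


def _shortest_tree(net: "ReactionNetwork"):
    """Deterministic multi-source Dijkstra over directed edges with
    resonance edges at cost zero.

    Ties are broken lexicographically: among equal-cost predecessors the
    smallest (predecessor key, edge repr) wins, so routes are independent
    of edge insertion order.  Returns (dist, parent_edge) maps.
    """
    adj: dict[str, list[ReactionEvent]] = {}
    for ev in net.edges:
        adj.setdefault(ev.reactant_key, []).append(ev)
    dist: dict[str, int] = {}
    parent: dict[str, Optional[ReactionEvent]] = {}
    heap = []
    for s in sorted(net.seeds):
        dist[s] = 0
        parent[s] = None
        heapq.heappush(heap, (0, s))
    while heap:
        d, key = heapq.heappop(heap)
        if d > dist.get(key, 1 << 30):
            continue
        for ev in sorted(adj.get(key, ()),
                         key=lambda e: (e.product_key, e.rtype.value, e.atoms)):
            nd = d + _edge_cost(ev)
            old = dist.get(ev.product_key)
            better = old is None or nd < old
            tie = (old == nd and parent.get(ev.product_key) is not None
                   and (key, ev.rtype.value, ev.atoms)
                   < (parent[ev.product_key].reactant_key,
                      parent[ev.product_key].rtype.value,
                      parent[ev.product_key].atoms))
            if better or tie:
                dist[ev.product_key] = nd
                parent[ev.product_key] = ev
                if better:
                    heapq.heappush(heap, (nd, ev.product_key))
    return dist, parent


def all_shortest_steps(net: "ReactionNetwork") -> dict[str, int]:
    """Paper-style step count (hops + 2) of every node in the network."""
    dist, _ = _shortest_tree(net)
    missing = set(net.nodes) - set(dist)
    if missing:
        raise ValueError(f"{len(missing)} nodes unreachable from the seeds")
    return {k: d + STEP_OFFSET for k, d in dist.items()}


def shortest_route(net: "ReactionNetwork", target: str) -> Route:
    """Shortest route from any seed to *target* (deterministic tie-break)."""
    if target not in net.nodes:
        raise KeyError(f"target {target!r} not in network")
    dist, parent = _shortest_tree(net)
    if target not in dist:
        raise ValueError(f"target {target!r} unreachable from the seeds")
    events: list[ReactionEvent] = []
    keys = [target]
    while parent[keys[-1]] is not None:
        ev = parent[keys[-1]]
        events.append(ev)
        keys.append(ev.reactant_key)
    return Route(node_keys=keys[::-1], events=events[::-1],
                 step_count=dist[target] + STEP_OFFSET)


def skeleton_min_steps(net: "ReactionNetwork",
                       table: pd.DataFrame) -> pd.DataFrame:
    """Recompute ``min_step`` of a skeleton table from shortest routes and
    return the updated copy (scatter-ready: ``min_step`` vs ``log10_n``)."""
    from .skeleton import extract_skeleton

    steps = all_shortest_steps(net)
    mins: dict[str, int] = {}
    for key, rec in net.nodes.items():
        fkey = extract_skeleton(rec.graph)
        s = steps[key]
        if fkey not in mins or s < mins[fkey]:
            mins[fkey] = s
    out = table.copy()
    out["min_step"] = [mins[k] for k in out["framework_key"]]
    return out
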