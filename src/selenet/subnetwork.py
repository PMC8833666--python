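"""Seed-based sub-network extraction and hub-to-seed path reporting.

A gene list (e.g. the selenoprotein family, or a differential-expression
selection) is mapped onto a parent interactome; the 1st- or 2nd-order
neighborhood of the mapped seeds is extracted as the subgraph *induced*
on all nodes within that hop distance — the neighborhood-selection
semantics of Cytoscape, so every parent edge between selected nodes is
kept.  Shortest connection paths from a hub back to each seed document
how a candidate hub touches the seed family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

from .errors import EmptySeedError, ParameterError
from .interactome import Interactome


def _as_graph(g) -> nx.Graph:
    return g.graph if isinstance(g, (Interactome, Subnetwork)) else g


class MapResult(NamedTuple):
    """Partition of an input gene list by network membership."""

    present: list[str]
    absent: list[str]
    duplicates: list[str]


def map_nodes(g: Interactome | nx.Graph, genes: Sequence[str]) -> MapResult:
    """Partition ``genes`` by membership in the network's node set.

    Input order is preserved and every occurrence is reported; symbols
    appearing more than once are additionally listed in ``duplicates``.
    """
    G = _as_graph(g)
    nodes = set(G.nodes)
    present, absent, seen, dups = [], [], set(), []
    for gene in genes:
        (present if gene in nodes else absent).append(gene)
        if gene in seen and gene not in dups:
            dups.append(gene)
        seen.add(gene)
    return MapResult(present, absent, dups)


@dataclass
class Subnetwork:
    """Induced neighborhood of a seed set within a parent network."""

    graph: nx.Graph
    seeds: set[str]        # seeds actually present in the parent
    order: int
    parent_id: str = "parent"
    absent_seeds: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def extract_neighborhood(
    g: Interactome | nx.Graph,
    seeds: Iterable[str],
    order: int = 1,
    parent_id: str = "parent",
) -> Subnetwork:
    """Extract the order-1 or order-2 neighborhood of a seed set.

    The node set is the mapped seeds plus every node within ``order``
    hops of any seed in the parent graph; the edge set is induced (all
    parent edges among selected nodes).  Seeds absent from the parent
    are recorded, not fatal; duplicate seeds collapse.

    Raises
    ------
    ParameterError
        ``order`` not in {1, 2}.
    EmptySeedError
        No seed maps onto the parent network.
    """
    if order not in (1, 2):
        raise ParameterError("order must be 1 or 2")
    G = _as_graph(g)
    seed_list = list(seeds)
    present = [s for s in seed_list if s in G]
    absent = [s for s in seed_list if s not in G]
    if not present:
        raise EmptySeedError("none of the seeds is present in the parent network")

    selected = set(present)
    frontier = set(present)
    for _ in range(order):
        frontier = {w for v in frontier for w in G.neighbors(v)} - selected
        selected |= frontier

    sub = G.subgraph(selected).copy()
    return Subnetwork(sub, seeds=set(present), order=order, parent_id=parent_id, absent_seeds=absent)


def seed_hub_paths(
    sn: Subnetwork | nx.Graph,
    hub: str,
    seeds: Iterable[str],
    max_len: int = 2,
) -> dict[str, list[list[str]]]:
    """All shortest hub-to-seed paths of length <= ``max_len``.

    For every seed present in the network, returns the complete set of
    distinct shortest paths from the hub, sorted lexicographically by
    their node sequence; a direct interaction appears as the length-1
    path ``[hub, seed]``.  Seeds farther than ``max_len`` (or
    unreachable, or absent) get an empty list.

    Raises
    ------
    ParameterError
        The hub is not a node of the network.
    """
    G = _as_graph(sn)
    if hub not in G:
        raise ParameterError(f"hub {hub!r} not present in the network")

    lengths = nx.single_source_shortest_path_length(G, hub, cutoff=max_len)
    out: dict[str, list[list[str]]] = {}
    for seed in seeds:
        if seed == hub:
            out[seed] = [[hub]]
            continue
        if seed not in G or seed not in lengths:
            out[seed] = []
            continue
        paths = [list(p) for p in nx.all_shortest_paths(G, hub, seed)]
        paths.sort()
        out[seed] = paths
    return out


def verify_shortest_paths(sn: Subnetwork | nx.Graph, paths: dict[str, list[list[str]]], hub: str) -> bool:
    """Re-check every reported path by breadth-first distance.

    Each path must be a walk along existing edges whose length equals
    the BFS distance from the hub to the seed.
    """
    G = _as_graph(sn)
    dist = nx.single_source_shortest_path_length(G, hub)
    for seed, plist in paths.items():
        for p in plist:
            if p[0] != hub or p[-1] != seed:
                return False
            if len(p) - 1 != dist.get(seed):
                return False
            if any(not G.has_edge(a, b) for a, b in zip(p, p[1:])):
                return False
    return True
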