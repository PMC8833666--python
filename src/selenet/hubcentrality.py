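"""Eleven-measure topological hub scoring and consensus hub ranking.

Hub nodes of a protein-protein interaction network are identified by
scoring every node under eleven measures and then ranking nodes by how
often they reach a per-measure top-k list:

* local connectivity: degree, MNC, DMNC, MCC
* percolation robustness: EPC
* shortest-path based: BottleNeck, eccentricity, closeness (harmonic),
  radiality, betweenness, stress

Measure definitions follow the conventions of the Cytoscape hub-scoring
ecosystem.  Each tunable constant (the DMNC exponent, the EPC iteration
count and seed, the BottleNeck descendant fraction, the consensus k and
minimum-measure count) is an explicit parameter recorded in the output.

Degree, MNC, BottleNeck and stress are integer-valued; all scores are
finite and non-negative.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError, ResourceError

#: Canonical measure order used in tables and reports.
MEASURES = (
    "degree",
    "mnc",
    "dmnc",
    "mcc",
    "epc",
    "bottleneck",
    "eccentricity",
    "closeness",
    "radiality",
    "betweenness",
    "stress",
)


# ---------------------------------------------------------------------------
# individual measures
# ---------------------------------------------------------------------------

def degree_scores(g: nx.Graph) -> dict:
    """Neighbor count per node."""
    return dict(g.degree())


def mnc_dmnc_scores(g: nx.Graph, epsilon: float = 1.7) -> tuple[dict, dict]:
    """Maximum Neighborhood Component and its density-scaled variant.

    For node v, induce the subgraph on N(v) (v itself excluded).  MNC(v)
    is the node count of the largest connected component of that
    neighborhood; DMNC(v) = E_c / V_c**epsilon of the same component,
    defined as 0 when MNC(v) <= 1 (an edgeless or empty neighborhood).
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    mnc: dict = {}
    dmnc: dict = {}
    for v in g.nodes:
        nbrs = set(g.neighbors(v)) - {v}
        if not nbrs:
            mnc[v], dmnc[v] = 0, 0.0
            continue
        sub = g.subgraph(nbrs)
        comp = max(nx.connected_components(sub), key=len)
        vc = len(comp)
        mnc[v] = vc
        if vc <= 1:
            dmnc[v] = 0.0
        else:
            ec = sub.subgraph(comp).number_of_edges()
            dmnc[v] = ec / vc**epsilon
    return mnc, dmnc


def mcc_scores(g: nx.Graph, max_cliques: int = 2_000_000) -> dict:
    """Maximal Clique Centrality.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!.
    A bare edge that is itself maximal contributes 1 to each endpoint,
    so a node whose neighborhood is edgeless scores exactly its degree.
    Size-1 maximal cliques (isolated nodes) contribute nothing.

    Raises
    ------
    ResourceError
        More than ``max_cliques`` maximal cliques encountered; decompose
        the graph (e.g. per community) before scoring.
    """
    scores = dict.fromkeys(g.nodes, 0)
    seen = 0
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        seen += 1
        if seen > max_cliques:
            raise ResourceError(
                f"maximal clique enumeration exceeded budget ({max_cliques}); "
                "decompose the network before computing MCC"
            )
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def epc_scores(
    g: nx.Graph,
    iterations: int = 1000,
    seed: int = 0,
    return_se: bool = False,
) -> dict | tuple[dict, dict]:
    """Edge Percolated Component by Monte-Carlo edge percolation.

    For each realization every edge receives an independent Uniform(0,1)
    weight and one Uniform(0,1) threshold is drawn; edges with weight >=
    threshold are retained.  A node's contribution is the size of its
    connected component in the retained graph, and EPC(v) is the mean
    contribution over realizations.  An isolated node scores exactly 1.

    With ``return_se`` the Monte-Carlo standard error of each mean is
    returned as a second dict.
    """
    if iterations < 1:
        raise ParameterError("iterations must be >= 1")
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(index[a], index[b]) for a, b in g.edges], dtype=np.int64)
    n, m = len(nodes), len(edges)
    if m == 0:  # every node always alone in its component
        scores = dict.fromkeys(nodes, 1.0)
        return (scores, dict.fromkeys(nodes, 0.0)) if return_se else scores
    rng = np.random.default_rng(seed)

    sums = np.zeros(n)
    sq_sums = np.zeros(n)
    parent = np.empty(n, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    for _ in range(iterations):
        weights = rng.random(m)
        threshold = rng.random()
        kept = edges[weights >= threshold]
        parent[:] = np.arange(n)
        for a, b in kept:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        sizes = np.bincount([find(i) for i in range(n)], minlength=n)
        contrib = sizes[[find(i) for i in range(n)]]
        sums += contrib
        sq_sums += contrib.astype(float) ** 2

    means = sums / iterations
    scores = {v: float(means[i]) for v, i in index.items()}
    if not return_se:
        return scores
    var = sq_sums / iterations - means**2
    se = np.sqrt(np.maximum(var, 0.0) / iterations)
    return scores, {v: float(se[i]) for v, i in index.items()}


def _bfs_tree_lex(g: nx.Graph, s) -> tuple[dict, dict]:
    """Deterministic BFS shortest-path tree from s.

    Returns (dist, parent); the parent of each non-source node is the
    lexicographically smallest neighbor one level closer to the source,
    making the tree — and hence the BottleNeck score — reproducible.
    """
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in g.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    parent = {}
    for v, d in dist.items():
        if v == s:
            continue
        parent[v] = min(w for w in g.neighbors(v) if dist.get(w) == d - 1)
    return dist, parent


def bottleneck_scores(g: nx.Graph) -> dict:
    """BottleNeck centrality.

    One shortest-path tree is built from every source s.  A node v != s
    scores +1 for that source iff the number of tree nodes whose path to
    s passes through v (v's descendants) exceeds a quarter of the nodes
    reachable from s.  BN(v) is the count over all sources.
    """
    scores = dict.fromkeys(g.nodes, 0)
    for s in g.nodes:
        dist, parent = _bfs_tree_lex(g, s)
        n_s = len(dist)
        subtree = dict.fromkeys(dist, 1)
        for v in sorted(dist, key=dist.get, reverse=True):
            if v != s:
                subtree[parent[v]] += subtree[v]
        quarter = n_s / 4.0
        for v in dist:
            if v != s and subtree[v] - 1 > quarter:
                scores[v] += 1
    return scores


def geodesic_scores(g: nx.Graph) -> dict[str, dict]:
    """Five shortest-path centralities in one pass.

    * closeness: harmonic form, sum of 1/d(v,w) over reachable w
      (unreachable nodes contribute 0; an isolated node scores 0)
    * eccentricity: max distance within v's component (0 for a
      singleton component)
    * radiality: sum over component peers of (diam + 1 - d) / (n_c - 1)
    * betweenness: shortest-path betweenness over unordered pairs,
      endpoints excluded, unnormalised
    * stress: number of shortest paths with v strictly interior
    """
    closeness = dict(nx.harmonic_centrality(g))

    eccentricity: dict = {}
    radiality: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nc = len(comp)
        if nc == 1:
            v = next(iter(comp))
            eccentricity[v], radiality[v] = 0, 0.0
            continue
        ecc = nx.eccentricity(sub)
        diam = max(ecc.values())
        eccentricity.update(ecc)
        for v in comp:
            lengths = nx.single_source_shortest_path_length(sub, v)
            radiality[v] = sum(
                (diam + 1 - d) / (nc - 1) for w, d in lengths.items() if w != v
            )

    betweenness = nx.betweenness_centrality(g, normalized=False)

    # Stress via the Brandes dependency accumulation, adapted so the
    # per-source dependency of v is sigma(s, v) * (1 + delta(w)/sigma(s, w))
    # summed over tree successors w; summing over all sources double
    # counts each unordered pair.
    stress_acc = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        sigma = {s: 1.0}
        dist = {s: 0}
        preds: dict = {s: []}
        order = []
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    q.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] * (1.0 + delta[w] / sigma[w])
            if w != s:
                stress_acc[w] += delta[w]
    stress = {v: int(round(x / 2.0)) for v, x in stress_acc.items()}

    return {
        "closeness": closeness,
        "eccentricity": eccentricity,
        "radiality": radiality,
        "betweenness": betweenness,
        "stress": stress,
    }


# ---------------------------------------------------------------------------
# assembly and consensus ranking
# ---------------------------------------------------------------------------

@dataclass
class CentralityTable:
    """Node-by-measure score matrix plus the parameters that produced it."""

    scores: pd.DataFrame  # index: node symbols; columns: MEASURES
    epc_iterations: int
    epc_seed: int
    dmnc_epsilon: float

    @property
    def nodes(self) -> list:
        return list(self.scores.index)


def compute_centralities(
    g: nx.Graph,
    epc_iterations: int = 1000,
    seed: int = 0,
    dmnc_epsilon: float = 1.7,
    mcc_max_cliques: int = 2_000_000,
) -> CentralityTable:
    """Score every node under all eleven measures."""
    mnc, dmnc = mnc_dmnc_scores(g, epsilon=dmnc_epsilon)
    geo = geodesic_scores(g)
    cols = {
        "degree": degree_scores(g),
        "mnc": mnc,
        "dmnc": dmnc,
        "mcc": mcc_scores(g, max_cliques=mcc_max_cliques),
        "epc": epc_scores(g, iterations=epc_iterations, seed=seed),
        "bottleneck": bottleneck_scores(g),
        **geo,
    }
    nodes = sorted(g.nodes, key=str)
    df = pd.DataFrame({m: [cols[m][v] for v in nodes] for m in MEASURES}, index=nodes)
    return CentralityTable(df, epc_iterations=epc_iterations, epc_seed=seed, dmnc_epsilon=dmnc_epsilon)


@dataclass
class HubEntry:
    node: str
    n_measures: int
    mean_rank: float


@dataclass
class HubReport:
    """Per-measure top-k lists and the consensus hub ranking."""

    top_k: dict[str, list]
    consensus: list[HubEntry]
    k: int
    min_measures: int
    parameters: dict = field(default_factory=dict)

    @property
    def consensus_nodes(self) -> list:
        return [e.node for e in self.consensus]


def rank_hubs(table: CentralityTable, k: int = 10, min_measures: int = 6) -> HubReport:
    """Consensus hub ranking from a centrality table.

    Every measure contributes a top-k list: descending score for all
    measures except eccentricity, which ranks ascending (a small maximum
    distance means central); nodes in singleton components (eccentricity
    0 by convention) are ranked last there.  Ties break on the symbol.
    Consensus hubs are nodes present in the top-k of at least
    ``min_measures`` measures, ordered by membership count (desc), then
    mean rank across the measures where they appear (asc), then symbol.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if min_measures > len(MEASURES):
        raise ParameterError(f"min_measures cannot exceed {len(MEASURES)}")
    df = table.scores
    n = len(df)
    if k > n:
        warnings.warn(f"k={k} exceeds node count {n}; clamping to {n}", stacklevel=2)
        k = n

    top_k: dict[str, list] = {}
    rank_of: dict[str, dict] = {}
    for measure in MEASURES:
        s = df[measure]
        if measure == "eccentricity":
            key = s.replace(0, np.inf)  # singleton components rank last
            ordered = sorted(df.index, key=lambda v: (key[v], str(v)))
        else:
            ordered = sorted(df.index, key=lambda v: (-s[v], str(v)))
        top = ordered[:k]
        top_k[measure] = top
        rank_of[measure] = {v: r for r, v in enumerate(top, start=1)}

    counts: dict = {}
    ranks: dict = {}
    for measure in MEASURES:
        for v, r in rank_of[measure].items():
            counts[v] = counts.get(v, 0) + 1
            ranks.setdefault(v, []).append(r)

    consensus = [
        HubEntry(v, counts[v], float(np.mean(ranks[v])))
        for v in counts
        if counts[v] >= min_measures
    ]
    consensus.sort(key=lambda e: (-e.n_measures, e.mean_rank, str(e.node)))
    return HubReport(
        top_k=top_k,
        consensus=consensus,
        k=k,
        min_measures=min_measures,
        parameters={
            "epc_iterations": table.epc_iterations,
            "epc_seed": table.epc_seed,
            "dmnc_epsilon": table.dmnc_epsilon,
        },
    )
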