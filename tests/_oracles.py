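"""Independent brute-force oracles for the test suite.

Everything here is computed from first principles on adjacency sets —
Floyd-Warshall distances, recursive shortest-path enumeration, subset
clique enumeration — deliberately avoiding the BFS/Brandes/clique code
paths used by the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

INF = float("inf")


def adjacency(graph) -> dict:
    """Plain dict-of-sets adjacency from a networkx graph."""
    return {v: set(graph.neighbors(v)) for v in graph.nodes}


def distance_matrix(adj: dict) -> dict:
    """All-pairs distances by Floyd-Warshall (INF when unreachable)."""
    nodes = list(adj)
    d = {u: {v: (0 if u == v else (1 if v in adj[u] else INF)) for v in nodes} for u in nodes}
    for k in nodes:
        for i in nodes:
            dik = d[i][k]
            if dik == INF:
                continue
            for j in nodes:
                alt = dik + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    return d


def shortest_paths(adj: dict, dist: dict, s, t) -> list[list]:
    """All shortest s->t paths, enumerated recursively off the distance matrix."""
    if dist[s][t] == INF:
        return []
    if s == t:
        return [[s]]
    out = []
    for u in adj[s]:
        if dist[u][t] == dist[s][t] - 1:
            out.extend([[s] + p for p in shortest_paths(adj, dist, u, t)])
    return out


def geodesic_oracle(graph) -> dict[str, dict]:
    """closeness/eccentricity/radiality/betweenness/stress by enumeration."""
    adj = adjacency(graph)
    dist = distance_matrix(adj)
    nodes = list(adj)

    closeness = {v: sum(1.0 / dist[v][w] for w in nodes if w != v and dist[v][w] < INF) for v in nodes}

    eccentricity = {}
    radiality = {}
    comps: list[set] = []
    seen: set = set()
    for v in nodes:
        if v in seen:
            continue
        comp = {w for w in nodes if dist[v][w] < INF}
        comps.append(comp)
        seen |= comp
    for comp in comps:
        nc = len(comp)
        if nc == 1:
            v = next(iter(comp))
            eccentricity[v], radiality[v] = 0, 0.0
            continue
        diam = max(dist[u][w] for u in comp for w in comp)
        for v in comp:
            eccentricity[v] = max(dist[v][w] for w in comp)
            radiality[v] = sum((diam + 1 - dist[v][w]) / (nc - 1) for w in comp if w != v)

    betweenness = dict.fromkeys(nodes, 0.0)
    stress = dict.fromkeys(nodes, 0)
    for s, t in itertools.combinations(nodes, 2):
        paths = shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                betweenness[v] += through / len(paths)
                stress[v] += through
    return {
        "closeness": closeness,
        "eccentricity": eccentricity,
        "radiality": radiality,
        "betweenness": betweenness,
        "stress": stress,
    }


def mcc_oracle(graph) -> dict:
    """MCC by enumerating every vertex subset (use only for n <= 12)."""
    adj = adjacency(graph)
    nodes = list(adj)
    scores = dict.fromkeys(nodes, 0)
    for size in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            ss = set(subset)
            if not all(b in adj[a] for a, b in itertools.combinations(subset, 2)):
                continue
            # maximal iff no outside vertex is adjacent to every member
            if any(ss <= adj[w] for w in nodes if w not in ss):
                continue
            weight = math.factorial(size - 1)
            for v in subset:
                scores[v] += weight
    return scores


def logrank_oracle(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square from the observed/expected table."""
    pooled = sorted({t for t, e in zip(list(times_a) + list(times_b), list(events_a) + list(events_b)) if e == 1})
    obs_a = 0.0
    exp_a = 0.0
    var = 0.0
    for t in pooled:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        da = sum(1 for x, e in zip(times_a, events_a) if x == t and e == 1)
        db = sum(1 for x, e in zip(times_b, events_b) if x == t and e == 1)
        n, d = na + nb, da + db
        if n < 2 or d == 0:
            continue
        obs_a += da
        exp_a += d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (obs_a - exp_a) ** 2 / var if var > 0 else 0.0
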