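import networkx as nx
import numpy as np
import pandas as pd
import pytest

from selenet.clinical import IHCCohort


@pytest.fixture
def star4() -> nx.Graph:
    """Star with center 'C' and four leaves."""
    g = nx.Graph()
    g.add_edges_from([("C", "L1"), ("C", "L2"), ("C", "L3"), ("C", "L4")])
    return g


@pytest.fixture
def path3() -> nx.Graph:
    """Path A - B - C."""
    return nx.Graph([("A", "B"), ("B", "C")])


def random_graph(n: int, p: float, seed: int, connected: bool = False) -> nx.Graph:
    """Erdos-Renyi test graph, optionally resampled until connected."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if not connected or nx.is_connected(g):
            return g


def cohort_from_marginals(counts: dict[int, dict[str, list[int]]], markers=("SELENOS", "VCP")) -> IHCCohort:
    """Build an IHC cohort whose per-marker grade x intensity marginals
    match given counts: {grade: {marker: [n_weak, n_moderate, n_strong]}}.

    Joint intensities are assigned by aligning the two markers' sorted
    score vectors within each grade (the joint distribution is not
    constrained by marginal tables).
    """
    rows = []
    for grade, per_marker in sorted(counts.items()):
        vectors = {}
        for marker in markers:
            v: list[int] = []
            for intensity, k in zip((1, 2, 3), per_marker[marker]):
                v.extend([intensity] * k)
            vectors[marker] = sorted(v)
        n = len(vectors[markers[0]])
        assert all(len(v) == n for v in vectors.values())
        for i in range(n):
            rows.append(
                {
                    "grade": grade,
                    "ki67": 30.0 if grade == 2 else 45.0,
                    markers[0]: vectors[markers[0]][i],
                    markers[1]: vectors[markers[1]][i],
                }
            )
    data = pd.DataFrame(rows, index=pd.Index([f"P{i:03d}" for i in range(len(rows))], name="patient"))
    return IHCCohort(data)
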