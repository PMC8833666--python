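"""Parsing, merging and summarising multi-source interaction edge lists.

Protein-protein interaction databases distribute physical-interaction
evidence in slightly different flat-file dialects.  This module reads
those edge lists, normalises gene symbols, merges several sources into a
single undirected simple graph with per-edge provenance, and computes
the global topology statistics (density, mean degree, characteristic
path length, degree heterogeneity) used to judge whether a network is
small-world-like and hub-rich.

The graph model is deliberately minimal: undirected, unweighted, no
self-loops, no parallel edges.  All downstream centrality measures are
defined on exactly this model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import FormatError, ParameterError, StatisticsError

DIALECTS = ("sif", "tsv2", "mitab_min")


@dataclass(frozen=True)
class InteractionRecord:
    """One normalised pairwise interaction read from an input line."""

    gene_a: str
    gene_b: str
    source: str
    line_no: int

    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair in canonical (sorted) order."""
        a, b = self.gene_a, self.gene_b
        return (a, b) if a <= b else (b, a)


@dataclass
class ParseReport:
    """Bookkeeping emitted alongside the parsed records."""

    n_lines: int = 0
    n_records: int = 0
    n_blank_or_comment: int = 0
    n_isolated_nodes: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)


def _normalize(token: str) -> str:
    return token.strip().upper()


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from stream.splitlines()
    else:
        for line in stream:
            yield line.rstrip("\n")


def parse_interactions(
    stream: str | IO[str] | Iterable[str],
    dialect: str,
    source: str = "source",
    mitab_columns: tuple[int, int] = (0, 1),
    synonyms: Mapping[str, str] | None = None,
) -> tuple[list[InteractionRecord], ParseReport]:
    """Parse an interaction edge list into records.

    Parameters
    ----------
    stream
        Text, an open file, or any iterable of lines.
    dialect
        ``"sif"`` (``node relation target [target ...]``, one record per
        target), ``"tsv2"`` (first two tab-separated columns), or
        ``"mitab_min"`` (tab-separated; symbol columns selected by
        ``mitab_columns``; extra columns such as detection method are
        ignored).
    source
        Provenance label attached to every record.
    synonyms
        Optional symbol -> canonical-symbol table applied after the
        default trim/uppercase normalisation.

    Returns
    -------
    (records, report)
        Records in input order plus a :class:`ParseReport` listing
        blank/comment lines skipped and malformed lines with their line
        numbers.

    Raises
    ------
    ParameterError
        Unknown dialect.
    FormatError
        The stream yields zero parseable interaction records.
    """
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    def canon(token: str) -> str:
        sym = _normalize(token)
        if synonyms:
            sym = _normalize(synonyms.get(sym, sym))
        return sym

    records: list[InteractionRecord] = []
    report = ParseReport()
    for line_no, raw in enumerate(_iter_lines(stream), start=1):
        report.n_lines += 1
        line = raw.strip()
        if not line or line.startswith("#"):
            report.n_blank_or_comment += 1
            continue
        if dialect == "sif":
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f for f in fields if f.strip()]
            if len(fields) == 1:
                report.n_isolated_nodes += 1  # bare node line: no edge
                continue
            if len(fields) == 2:
                report.malformed.append((line_no, "SIF line with a relation but no target"))
                continue
            a = canon(fields[0])
            targets = [canon(t) for t in fields[2:]]
            if not a or any(not t for t in targets):
                report.malformed.append((line_no, "empty symbol after normalization"))
                continue
            for t in targets:
                records.append(InteractionRecord(a, t, source, line_no))
                report.n_records += 1
        else:
            fields = line.split("\t")
            if dialect == "tsv2":
                ia, ib = 0, 1
            else:
                ia, ib = mitab_columns
            if len(fields) <= max(ia, ib):
                report.malformed.append((line_no, f"expected >= {max(ia, ib) + 1} tab-separated columns"))
                continue
            a, b = canon(fields[ia]), canon(fields[ib])
            if not a or not b:
                report.malformed.append((line_no, "empty symbol after normalization"))
                continue
            records.append(InteractionRecord(a, b, source, line_no))
            report.n_records += 1

    if not records:
        raise FormatError(f"no parseable interaction lines (dialect={dialect!r})")
    return records, report


@dataclass
class Interactome:
    """Undirected simple interaction graph with per-edge provenance.

    ``graph`` is a :class:`networkx.Graph`; every edge carries a
    ``sources`` attribute holding the set of source identifiers that
    reported it.
    """

    graph: nx.Graph
    n_self_loops_dropped: int = 0
    n_duplicates_collapsed: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def provenance(self, a: str, b: str) -> set[str]:
        return set(self.graph.edges[a, b]["sources"])

    def _check(self) -> None:
        assert not list(nx.selfloop_edges(self.graph))


def merge_interactomes(record_lists: Sequence[Sequence[InteractionRecord]]) -> Interactome:
    """Union several per-source record lists into one Interactome.

    Self-loops are dropped (counted), duplicate unordered pairs collapse
    with their provenance sets unioned.  The operation is idempotent and
    invariant under source-order permutation.
    """
    if not record_lists:
        raise ParameterError("at least one source record list is required")
    g = nx.Graph()
    n_loops = 0
    n_dups = 0
    for records in record_lists:
        for rec in records:
            a, b = rec.pair()
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                n_dups += 1
                g.edges[a, b]["sources"].add(rec.source)
            else:
                g.add_edge(a, b, sources={rec.source})
    return Interactome(g, n_self_loops_dropped=n_loops, n_duplicates_collapsed=n_dups)


@dataclass
class NetworkStats:
    """Global topology summary of one named network."""

    n_nodes: int
    n_edges: int
    density: float
    avg_neighbors: float
    char_path_length: float
    heterogeneity: float
    n_components: int
    path_length_method: str = "exact"
    path_length_sample_size: int | None = None
    path_length_seed: int | None = None


def _as_graph(g: Interactome | nx.Graph) -> nx.Graph:
    return g.graph if isinstance(g, Interactome) else g


def network_stats(
    g: Interactome | nx.Graph,
    path_length_exact_limit: int = 2000,
    n_sample_sources: int = 1000,
    seed: int = 0,
) -> NetworkStats:
    """Compute density, mean degree, heterogeneity and path length.

    * density = 2E / (N (N-1))
    * avg_neighbors = mean degree = 2E / N
    * heterogeneity = population sd(degree) / mean(degree) — the
      coefficient of variation of the degree distribution; 0 iff the
      graph is regular.
    * char_path_length = mean shortest-path distance over all unordered
      *connected* node pairs.  Exact (BFS from every node) when
      N <= ``path_length_exact_limit``; otherwise estimated by BFS from
      ``n_sample_sources`` uniformly sampled sources, with the seed and
      sample size recorded in the result.

    Raises
    ------
    StatisticsError
        Fewer than two nodes.
    """
    G = _as_graph(g)
    n, m = G.number_of_nodes(), G.number_of_edges()
    if n < 2:
        raise StatisticsError("network statistics are undefined for graphs with < 2 nodes")

    degrees = np.array([d for _, d in G.degree()], dtype=float)
    density = 2.0 * m / (n * (n - 1))
    avg_neighbors = 2.0 * m / n
    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0

    # Mean distance over source-target visits equals the mean over
    # unordered connected pairs (each pair contributes symmetrically),
    # so no pair deduplication is needed in either branch.
    if n <= path_length_exact_limit:
        sources: list = list(G.nodes)
        method, sample_size, used_seed = "exact", None, None
    else:
        rng = np.random.default_rng(seed)
        node_list = list(G.nodes)
        k = min(n_sample_sources, n)
        idx = rng.choice(n, size=k, replace=False)
        sources = [node_list[i] for i in idx]
        method, sample_size, used_seed = "sampled", k, seed

    total = 0.0
    pairs = 0
    for s in sources:
        lengths = nx.single_source_shortest_path_length(G, s)
        total += sum(lengths.values())
        pairs += len(lengths) - 1  # exclude distance-0 self pair
    cpl = (total / pairs) if pairs else math.nan

    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        density=density,
        avg_neighbors=avg_neighbors,
        char_path_length=cpl,
        heterogeneity=heterogeneity,
        n_components=nx.number_connected_components(G),
        path_length_method=method,
        path_length_sample_size=sample_size,
        path_length_seed=used_seed,
    )


def write_sif(g: Interactome | nx.Graph, path, relation: str = "pp") -> None:
    """Write the graph as a deterministic (sorted) SIF edge list."""
    G = _as_graph(g)
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in sorted(nx.isolates(G)):
            fh.write(f"{v}\n")


def write_graphml(g: Interactome | nx.Graph, path) -> None:
    G = _as_graph(g).copy()
    for _, _, data in G.edges(data=True):
        if "sources" in data:
            data["sources"] = ",".join(sorted(data["sources"]))
    nx.write_graphml(G, path)


def read_graph(path, dialect: str | None = None) -> nx.Graph:
    """Read a SIF or GraphML file back into a plain graph."""
    path = str(path)
    if dialect == "graphml" or (dialect is None and path.endswith(".graphml")):
        return nx.read_graphml(path)
    with open(path) as fh:
        text = fh.read()
    g = nx.Graph()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 1:
            g.add_node(_normalize(fields[0]))
        elif len(fields) >= 3:
            a = _normalize(fields[0])
            for t in fields[2:]:
                g.add_edge(a, _normalize(t))
    return g
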