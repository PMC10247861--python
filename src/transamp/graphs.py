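"""Graph representation, construction, I/O and isomorphism utilities.

Graphs are plain :class:`networkx.Graph` objects: simple, undirected,
unweighted, with 0-based integer vertex labels. Edges are unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import igraph as ig
import networkx as nx
import numpy as np

from ._core import adjacency, normalized_spectrum_adj

__all__ = [
    "check_graph",
    "DegreeInfo",
    "degrees",
    "is_connected",
    "remove_edge",
    "complement",
    "cycle_partitions",
    "regulars_from_cycle_partitions",
    "enumerate_regular_graphs",
    "canonical_key",
    "cospectral_key",
    "read_graph6",
    "write_graph6",
    "read_edgelist",
    "write_edgelist",
]


def check_graph(g: nx.Graph) -> nx.Graph:
    """Validate the simple-undirected-graph invariants; returns ``g``."""
    if g.is_directed() or g.is_multigraph():
        raise ValueError("expected a simple undirected graph")
    if any(u == v for u, v in g.edges()):
        raise ValueError("self-loops are not allowed")
    return g


@dataclass(frozen=True)
class DegreeInfo:
    degrees: tuple[int, ...]
    max: int
    min: int
    mean: float


def degrees(g: nx.Graph) -> DegreeInfo:
    """Per-vertex degrees plus (max, min, mean), vertices in sorted order."""
    ks = tuple(int(g.degree(v)) for v in sorted(g.nodes()))
    return DegreeInfo(ks, max(ks), min(ks), sum(ks) / len(ks))


def is_connected(g: nx.Graph) -> bool:
    return g.number_of_nodes() > 0 and nx.is_connected(g)


def remove_edge(g: nx.Graph, i, j) -> nx.Graph:
    """New graph with the single edge (i, j) removed; labels preserved."""
    if not g.has_edge(i, j):
        raise ValueError(f"edge ({i}, {j}) not present")
    h = g.copy()
    h.remove_edge(i, j)
    return h


def complement(g: nx.Graph) -> nx.Graph:
    return nx.complement(g)


def cycle_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """Partitions of ``n`` into parts >= 3, ascending-sorted tuples in lex order."""

    def rec(remaining: int, minimum: int, prefix: tuple[int, ...]):
        if remaining == 0:
            yield prefix
            return
        for part in range(minimum, remaining + 1):
            if remaining - part in (1, 2):
                continue
            yield from rec(remaining - part, part, prefix + (part,))

    yield from rec(n, 3, ())


def regulars_from_cycle_partitions(n: int) -> list[nx.Graph]:
    """All connected (n-3)-regular graphs built as complements of disjoint cycles.

    One graph per partition of ``n`` into cycle lengths >= 3; pairwise
    non-isomorphic by construction (distinct cycle-type multisets). Output is
    ordered by the sorted-partition lexicographic order.
    """
    if n < 6:
        raise ValueError("need n >= 6")
    out = []
    for parts in cycle_partitions(n):
        g = nx.Graph()
        offset = 0
        for a in parts:
            for i in range(a):
                g.add_edge(offset + i, offset + (i + 1) % a)
            offset += a
        h = nx.complement(g)
        if nx.is_connected(h):
            h.graph["partition"] = parts
            h.graph["label"] = "C(" + ",".join(map(str, parts)) + ")^c"
            out.append(h)
    return out


def enumerate_regular_graphs(n: int, k: int, max_vertices: int = 10) -> list[nx.Graph]:
    """All connected pairwise non-isomorphic k-regular graphs on n vertices.

    Plain backtracking over labeled graphs (vertices completed in increasing
    order) with canonical-key deduplication; intended for small n only.
    """
    if n > max_vertices:
        raise ValueError(f"enumeration supported for n <= {max_vertices}")
    if n * k % 2 != 0 or k >= n or k < 0:
        return []

    results: dict[str, nx.Graph] = {}
    need = [k] * n
    edges: list[tuple[int, int]] = []

    def rec():
        try:
            i = next(v for v in range(n) if need[v] > 0)
        except StopIteration:
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            if nx.is_connected(g):
                results.setdefault(canonical_key(g), g)
            return
        avail = [j for j in range(i + 1, n) if need[j] > 0]
        if len(avail) < need[i]:
            return
        from itertools import combinations

        saved = need[i]
        for combo in combinations(avail, saved):
            need[i] = 0
            for j in combo:
                need[j] -= 1
                edges.append((i, j))
            rec()
            for j in combo:
                need[j] += 1
                edges.pop()
            need[i] = saved

    rec()
    return list(results.values())


def canonical_key(g: nx.Graph) -> str:
    """Canonical-labeling certificate: equal strings iff graphs are isomorphic."""
    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    igg = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges()])
    cg = igg.permute_vertices(igg.canonical_permutation())
    edge_list = sorted(tuple(sorted(e)) for e in cg.get_edgelist())
    return f"{len(nodes)}|" + ";".join(f"{u},{v}" for u, v in edge_list)


def cospectral_key(g: nx.Graph, decimals: int = 9) -> str:
    """Rounded sorted normalized-Laplacian spectrum, serialized.

    Equal for isomorphic graphs; a cheap proxy for isomorphism (cospectral
    non-isomorphic mates collide, but such pairs are rare for the normalized
    Laplacian).
    """
    lam = np.round(normalized_spectrum_adj(adjacency(g)), decimals) + 0.0
    return ",".join(f"{x:.{decimals}f}" for x in lam)


def read_graph6(path) -> list[nx.Graph]:
    """Read a graph6 file (nauty dialect, one graph per line, no header)."""
    graphs = []
    with open(path, "rb") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(b">>graph6<<"):
                line = line[len(b">>graph6<<"):]
            try:
                graphs.append(nx.from_graph6_bytes(line))
            except Exception as exc:
                raise ValueError(f"malformed graph6 record at line {lineno}: {exc}") from exc
    return graphs


def write_graph6(graphs: Iterable[nx.Graph], path) -> None:
    with open(path, "wb") as fh:
        for g in graphs:
            fh.write(nx.to_graph6_bytes(g, header=False))


def read_edgelist(path) -> nx.Graph:
    """Plain-text edge list, one '"i j"' pair per line, 0-based."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                i, j = map(int, line.split())
            except ValueError as exc:
                raise ValueError(f"malformed edge at line {lineno}: {line!r}") from exc
            g.add_edge(i, j)
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u} {v}\n")
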