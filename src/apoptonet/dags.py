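"""Labelled DAG helpers used by scoring, search and simulation.

DAGs are held as :class:`networkx.DiGraph` objects whose nodes are gene
labels (strings).  The functions here add the small amount of structure the
rest of the package needs on top of networkx: construction with an
acyclicity check, parent lookup, skeleton / v-structure extraction for
Markov-equivalence comparisons, and edge-list serialization.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

__all__ = [
    "make_dag",
    "check_dag",
    "parents",
    "skeleton",
    "v_structures",
    "markov_equivalent",
    "write_edge_list",
    "read_edge_list",
]


def make_dag(nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()) -> nx.DiGraph:
    """Build a directed acyclic graph and verify acyclicity.

    Parameters
    ----------
    nodes
        Node labels; order is preserved and defines the default node order
        used elsewhere (e.g. covariance matrices).
    edges
        Directed (parent, child) pairs.  Every endpoint must be in *nodes*.
    """
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        if u not in g or v not in g:
            raise ValueError(f"edge ({u!r}, {v!r}) references a node not in the node list")
        g.add_edge(u, v)
    check_dag(g)
    return g


def check_dag(g: nx.DiGraph) -> None:
    """Raise ``ValueError`` if *g* contains a directed cycle or self-loop."""
    if any(u == v for u, v in g.edges):
        raise ValueError("self-loops are not allowed in a DAG")
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"graph contains a directed cycle: {cycle}")


def parents(g: nx.DiGraph, node: str) -> tuple[str, ...]:
    """Parents of *node* in *g*, sorted for determinism."""
    return tuple(sorted(g.predecessors(node)))


def skeleton(g: nx.DiGraph) -> frozenset[frozenset[str]]:
    """Undirected edge set of *g* as a frozenset of unordered pairs."""
    return frozenset(frozenset((u, v)) for u, v in g.edges)


def v_structures(g: nx.DiGraph) -> frozenset[tuple[str, str, str]]:
    """Immoralities of *g*: (a, c, b) with a->c<-b and a, b non-adjacent.

    The pair (a, b) is returned in sorted order so the set is canonical.
    """
    out = set()
    for c in g.nodes:
        pa = sorted(g.predecessors(c))
        for i in range(len(pa)):
            for j in range(i + 1, len(pa)):
                a, b = pa[i], pa[j]
                if not (g.has_edge(a, b) or g.has_edge(b, a)):
                    out.add((a, c, b))
    return frozenset(out)


def markov_equivalent(g1: nx.DiGraph, g2: nx.DiGraph) -> bool:
    """True when the two DAGs share skeleton and v-structures.

    By Verma and Pearl's characterization this is exactly Markov
    equivalence for DAGs over the same node set.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("DAGs are over different node sets")
    return skeleton(g1) == skeleton(g2) and v_structures(g1) == v_structures(g2)


def write_edge_list(g: nx.DiGraph, path) -> None:
    """Write a DAG as a 2-column TSV edge list plus isolated-node lines.

    Isolated nodes are written as a single-column line so the node set
    round-trips.
    """
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
        for n in sorted(isolated):
            fh.write(f"{n}\n")


def read_edge_list(path) -> nx.DiGraph:
    """Read a DAG written by :func:`write_edge_list`."""
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                nodes.append(parts[0])
            elif len(parts) == 2:
                edges.append((parts[0], parts[1]))
            else:
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(parts)}")
    for u, v in edges:
        for n in (u, v):
            if n not in nodes:
                nodes.append(n)
    return make_dag(nodes, edges)
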