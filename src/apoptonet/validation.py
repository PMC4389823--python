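"""Validation of predicted interactions against a curated reference network.

Each predicted edge is classified, ignoring direction, as *direct* (the
pair is a reference edge), *indirect* (no direct edge but a path exists via
intermediate genes; all shortest paths are recorded) or *unsupported* (no
path, or an endpoint absent from the reference).  The union of endpoints
and shortest-path intermediates of the supported edges forms the evidence
subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import read_network

__all__ = ["EdgeEvidence", "ValidationReport", "load_reference", "classify_edges", "evidence_subnetwork"]


@dataclass
class EdgeEvidence:
    """Classification of one predicted edge."""

    source: str
    target: str
    status: str  # direct | indirect | unsupported
    shortest_paths: list[list[str]] = field(default_factory=list)

    @property
    def path_length(self) -> int | None:
        return len(self.shortest_paths[0]) - 1 if self.shortest_paths else None


@dataclass
class ValidationReport:
    """Per-edge evidence plus summary counts (a partition of the edges)."""

    edges: list[EdgeEvidence]
    unresolved_nodes: list[str]

    @property
    def counts(self) -> dict[str, int]:
        out = {"direct": 0, "indirect": 0, "unsupported": 0}
        for e in self.edges:
            out[e.status] += 1
        return out

    @property
    def n_supported(self) -> int:
        c = self.counts
        return c["direct"] + c["indirect"]


def load_reference(path) -> nx.Graph:
    """Read a reference interaction network (edge-list TSV or SIF).

    Undirected simple graph; symbols uppercased; self-loops and duplicate
    edges dropped (logged by :func:`apoptonet.io.read_network`).
    """
    return read_network(path)


def classify_edges(predicted: nx.DiGraph | nx.Graph, reference: nx.Graph) -> ValidationReport:
    """Classify every predicted edge as direct / indirect / unsupported.

    Prediction direction is ignored.  For indirect edges *all* shortest
    paths between the endpoints in the reference graph are recorded (only
    shortest paths count as indirect evidence).
    """
    unresolved = sorted(
        {n.upper() for e in predicted.edges for n in e} - set(reference.nodes)
    )
    evidences: list[EdgeEvidence] = []
    for u, v in sorted(predicted.edges):
        uu, vv = u.upper(), v.upper()
        if uu not in reference or vv not in reference:
            evidences.append(EdgeEvidence(u, v, "unsupported"))
        elif reference.has_edge(uu, vv):
            evidences.append(EdgeEvidence(u, v, "direct", [[uu, vv]]))
        elif nx.has_path(reference, uu, vv):
            paths = [list(p) for p in nx.all_shortest_paths(reference, uu, vv)]
            evidences.append(EdgeEvidence(u, v, "indirect", paths))
        else:
            evidences.append(EdgeEvidence(u, v, "unsupported"))
    return ValidationReport(edges=evidences, unresolved_nodes=unresolved)


def evidence_subnetwork(report: ValidationReport, reference: nx.Graph) -> nx.Graph:
    """Reference subgraph carrying the evidence for supported predictions.

    Contains every endpoint of a direct or indirect predicted edge plus all
    nodes and edges lying on any recorded shortest path.
    """
    sub = nx.Graph()
    for ev in report.edges:
        if ev.status == "unsupported":
            continue
        for path in ev.shortest_paths:
            sub.add_nodes_from(path)
            for a, b in zip(path, path[1:]):
                if not reference.has_edge(a, b):  # pragma: no cover - internal consistency
                    raise RuntimeError(f"recorded path step {a}-{b} is not a reference edge")
                sub.add_edge(a, b)
    return sub
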