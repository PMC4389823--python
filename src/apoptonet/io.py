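"""Readers and writers for the package's fixed file dialects.

Formats: expression matrices as TSV (first column = row id, header =
sample ids), sample designs as 2-column TSV, gene sets as GMT, interaction
networks as 2-column edge-list TSV or 3-column SIF, DAGs as edge lists
(see :mod:`apoptonet.dags`).  Lines starting with ``#`` are treated as
comments everywhere, which is where pipeline provenance headers live.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_sif",
    "write_network_tsv",
]


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}={v}" for k, v in provenance.items()]


def write_expression_tsv(expr: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a genes x samples matrix; first column holds row ids."""
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        expr.to_csv(fh, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if expr.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row ids")
    if expr.isna().any().any():
        raise ValueError(f"{path}: missing values are not allowed")
    return expr


def write_design_tsv(design, path, provenance: dict | None = None) -> None:
    """Write a SampleDesign as a 2-column TSV (sample, group)."""
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write("sample\tgroup\n")
        for s, g in zip(design.sample_ids, design.groups):
            fh.write(f"{s}\t{g}\n")


def read_design_tsv(path):
    from .datasets import SampleDesign

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: expected columns 'sample' and 'group'")
    return SampleDesign(tuple(df["sample"]), tuple(df["group"]))


def write_gmt(gene_sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    """Write gene sets in GMT: name, description, then one gene per column."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description and >=1 gene")
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


def read_network(path) -> nx.Graph:
    """Read an undirected interaction network from edge-list TSV or SIF.

    2 columns = edge list (source, target); 3 columns = SIF (source,
    interaction, target).  Symbols are uppercased; self-loops and duplicate
    edges are dropped with a logged count.
    """
    g = nx.Graph()
    dropped_self = dropped_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("source\t"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                node = parts[0].strip().upper()
                if not node:
                    raise ValueError(f"{path}:{lineno}: empty node symbol")
                g.add_node(node)
                continue
            if len(parts) == 2:
                u, v = parts
            elif len(parts) == 3:
                u, _, v = parts
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 1 (isolated node), 2 (edge list) "
                    f"or 3 (SIF) columns, got {len(parts)}"
                )
            u, v = u.strip().upper(), v.strip().upper()
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty node symbol")
            if u == v:
                dropped_self += 1
                continue
            if g.has_edge(u, v):
                dropped_dup += 1
                continue
            g.add_edge(u, v)
    if dropped_self or dropped_dup:
        logger.info(
            "read_network(%s): dropped %d self-loops and %d duplicate edges",
            path, dropped_self, dropped_dup,
        )
    return g


def write_sif(g: nx.Graph | nx.DiGraph, path, interaction: str = "interacts", provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def write_network_tsv(g: nx.Graph | nx.DiGraph, path, provenance: dict | None = None) -> None:
    """Write a network as a 2-column TSV edge list (plus isolated nodes)."""
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write("source\ttarget\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")
        for n in sorted(n for n in g.nodes if g.degree(n) == 0):
            fh.write(f"{n}\n")

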