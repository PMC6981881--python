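"""Assembly of the miRNA-gene-lincRNA regulatory network and ceRNA candidate set.

Nodes are typed (miRNA, mRNA, lincRNA); edges are typed: ``represses``
(directed miRNA -> mRNA), ``coexpressed`` (undirected lincRNA - mRNA, weighted
by the correlation), and ``shares_mirna`` (undirected mRNA - mRNA through a
common targeting miRNA). A ceRNA candidate is any other target of a miRNA
that also targets the focal gene, flagged when it falls in the focal gene's
expression cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .duplex import DuplexError

__all__ = ["RegulatoryNetwork", "CeRNACandidate", "build_network", "cerna_candidates"]

NODE_TYPES = ("miRNA", "mRNA", "lincRNA")
EDGE_TYPES = ("represses", "coexpressed", "shares_mirna")
_DIRECTED = {"represses"}


class RegulatoryNetwork:
    """A typed graph with directed repression edges and undirected association edges.

    Backed by a networkx DiGraph; undirected edge types are stored once under
    canonically ordered endpoints and treated as symmetric by the accessors.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise DuplexError(f"unknown node type {node_type!r}")
        existing = self.graph.nodes.get(node_id)
        if existing and existing["node_type"] != node_type:
            raise DuplexError(
                f"node {node_id!r} already typed {existing['node_type']!r}, not {node_type!r}"
            )
        self.graph.add_node(node_id, node_type=node_type)

    def add_edge(self, u: str, v: str, edge_type: str, **attrs) -> None:
        if edge_type not in EDGE_TYPES:
            raise DuplexError(f"unknown edge type {edge_type!r}")
        if u == v:
            raise DuplexError(f"self-edge on {u!r} rejected")
        for n in (u, v):
            if n not in self.graph:
                raise DuplexError(f"edge endpoint {n!r} is not a node")
        if edge_type not in _DIRECTED:
            u, v = sorted((u, v))
        if self.graph.has_edge(u, v) and self.graph.edges[u, v]["edge_type"] == edge_type:
            return  # dedupe
        self.graph.add_edge(u, v, edge_type=edge_type, **attrs)

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type
        )

    def edges_of_type(self, edge_type: str) -> list[tuple[str, str]]:
        return sorted(
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d["edge_type"] == edge_type
        )

    # -- serialization ----------------------------------------------------
    def to_edgelist(self) -> list[tuple[str, str, str, str, str]]:
        """Rows (source, source_type, edge_type, target, target_type), sorted."""
        rows = []
        for u, v, d in self.graph.edges(data=True):
            rows.append(
                (
                    u,
                    self.graph.nodes[u]["node_type"],
                    d["edge_type"],
                    v,
                    self.graph.nodes[v]["node_type"],
                )
            )
        return sorted(rows)

    def write_edgelist(self, path: str | Path) -> None:
        lines = ["source\tsource_type\tedge_type\ttarget\ttarget_type"]
        lines += ["\t".join(r) for r in self.to_edgelist()]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    @classmethod
    def from_edgelist(cls, rows: Iterable[tuple[str, str, str, str, str]]) -> "RegulatoryNetwork":
        net = cls()
        for u, ut, etype, v, vt in rows:
            net.add_node(u, ut)
            net.add_node(v, vt)
            net.add_edge(u, v, etype)
        return net

    def is_isomorphic_to(self, other: "RegulatoryNetwork") -> bool:
        return self.to_edgelist() == other.to_edgelist() and set(
            self.graph.nodes
        ) == set(other.graph.nodes)


def build_network(
    focal_gene: str,
    mirna_targets: Iterable[tuple[str, str]],
    lincrna_pairs: Iterable[tuple[str, str, float]],
) -> RegulatoryNetwork:
    """Assemble the repression + co-expression network around a focal gene.

    ``mirna_targets``: (miRNA id, target mRNA id) pairs that passed the
    duplex filters. ``lincrna_pairs``: (lincRNA id, gene id, r) from the
    trans screen. Duplicates collapse to single edges.
    """
    mirna_targets = list(mirna_targets)
    lincrna_pairs = list(lincrna_pairs)
    net = RegulatoryNetwork()
    if not mirna_targets and not lincrna_pairs:
        warnings.warn("no miRNA targets and no lincRNA pairs: empty network", stacklevel=2)
        return net
    mentioned = {t for _, t in mirna_targets} | {g for _, g, _ in lincrna_pairs}
    if focal_gene not in mentioned:
        raise DuplexError(
            f"focal gene {focal_gene!r} appears in neither the miRNA targets nor the lincRNA pairs"
        )
    for mirna, target in mirna_targets:
        net.add_node(mirna, "miRNA")
        net.add_node(target, "mRNA")
        net.add_edge(mirna, target, "represses")
    for lnc, gene, r in lincrna_pairs:
        net.add_node(lnc, "lincRNA")
        net.add_node(gene, "mRNA")
        net.add_edge(lnc, gene, "coexpressed", weight=float(r))
    return net


@dataclass(frozen=True)
class CeRNACandidate:
    gene_id: str
    shared_mirna: str
    same_cluster_as_focal: bool
    annotation_label: str = ""


def cerna_candidates(
    focal_gene: str,
    mirna_targets: Iterable[tuple[str, str]],
    cluster_labels: Mapping[str, int],
    annotations: Mapping[str, str] | None = None,
) -> list[CeRNACandidate]:
    """Other targets of the focal gene's miRNAs, flagged by shared-cluster membership.

    "Similar expression pattern" is operationalized as carrying the same
    cluster label as the focal gene at the configured dendrogram cut.
    """
    if focal_gene not in cluster_labels:
        raise DuplexError(f"focal gene {focal_gene!r} has no cluster label")
    targets = list(mirna_targets)
    focal_mirnas = {m for m, t in targets if t == focal_gene}
    focal_cluster = cluster_labels[focal_gene]
    out = []
    seen = set()
    for mirna, gene in targets:
        if mirna not in focal_mirnas or gene == focal_gene or (mirna, gene) in seen:
            continue
        seen.add((mirna, gene))
        same = cluster_labels.get(gene) == focal_cluster
        label = (annotations or {}).get(gene, "")
        out.append(CeRNACandidate(gene, mirna, same, label))
    out.sort(key=lambda c: (c.shared_mirna, c.gene_id))
    return out
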