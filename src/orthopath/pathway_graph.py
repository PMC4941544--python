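"""Typed directed pathway graphs and miRNA-target augmentation.

A pathway is a directed graph whose nodes are genes (and, after
augmentation, miRNAs) and whose edges carry a relation type such as
``activation`` or ``repression``.  Augmentation adds, for every miRNA with
at least one target on the pathway, a miRNA node and a repression edge to
each of its on-pathway targets — the graph a topology-aware impact analysis
then propagates expression changes through.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover - avoid circular import at runtime
    from orthopath.io_formats import TargetMap

#: signed interaction weights: +1 activation-like, -1 repression-like,
#: 0 neutral.  Relations outside this table must be mapped explicitly.
DEFAULT_WEIGHT_TABLE: dict[str, float] = {
    "activation": 1.0,
    "expression": 1.0,
    "repression": -1.0,
    "inhibition": -1.0,
    "binding": 0.0,
}

NODE_TYPES = frozenset({"gene", "mirna"})


def edge_weight(relation: str, weight_table: dict[str, float] | None = None) -> float:
    """Signed strength of an interaction type.

    Raises for relations absent from the table (fail-fast rather than a
    silent zero weight).
    """
    table = DEFAULT_WEIGHT_TABLE if weight_table is None else weight_table
    if relation not in table:
        raise KeyError(
            f"relation '{relation}' has no weight; known relations: "
            f"{sorted(table)}"
        )
    return table[relation]


@dataclass
class PathwayGraph:
    """A typed directed pathway graph.

    ``nodes`` maps node id -> node type (``gene`` or ``mirna``);
    ``edges`` is a set of (src, dst, relation) triples.
    """

    pathway_id: str
    name: str = ""
    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def add_node(self, node_id: str, node_type: str = "gene") -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"node_type must be one of {sorted(NODE_TYPES)}")
        prev = self.nodes.get(node_id)
        if prev is not None and prev != node_type:
            raise ValueError(
                f"pathway {self.pathway_id}: node '{node_id}' already typed "
                f"'{prev}', cannot retype to '{node_type}'"
            )
        self.nodes[node_id] = node_type

    def add_edge(self, src: str, dst: str, relation: str) -> None:
        for n in (src, dst):
            if n not in self.nodes:
                self.add_node(n, "gene")
        self.edges.add((src, dst, relation))

    def gene_nodes(self) -> set[str]:
        return {n for n, t in self.nodes.items() if t == "gene"}

    def mirna_nodes(self) -> set[str]:
        return {n for n, t in self.nodes.items() if t == "mirna"}

    def to_networkx(self) -> nx.MultiDiGraph:
        """Export as a networkx multigraph (parallel relations kept)."""
        g = nx.MultiDiGraph(pathway_id=self.pathway_id, name=self.name)
        for n, t in self.nodes.items():
            g.add_node(n, node_type=t)
        for src, dst, rel in sorted(self.edges):
            g.add_edge(src, dst, relation=rel)
        return g

    def copy(self) -> "PathwayGraph":
        return PathwayGraph(
            pathway_id=self.pathway_id,
            name=self.name,
            nodes=dict(self.nodes),
            edges=set(self.edges),
        )


def augment_pathway(p: PathwayGraph, targets: "TargetMap") -> PathwayGraph:
    """Extend a pathway with miRNA nodes and miRNA->target edges.

    For each miRNA whose target set intersects the pathway's nodes, the
    miRNA is added as a node and connected to each on-pathway target with
    the recorded interaction type (``repression`` by default).  miRNAs with
    no target on the pathway are not added; existing nodes and edges are
    untouched, so augmenting twice with the same map is a no-op.
    """
    out = p.copy()
    node_ids = set(p.nodes)
    for (mirna, gene), relation in sorted(targets.records.items()):
        if gene in node_ids:
            out.add_node(mirna, "mirna")
            out.add_edge(mirna, gene, relation)
    return out


def downstream_counts(p: PathwayGraph) -> dict[str, int]:
    """Number of distinct successors of each node (out-degree).

    Used to split a node's perturbation evenly among its downstream
    neighbours during propagation.
    """
    succ: dict[str, set[str]] = {n: set() for n in p.nodes}
    for src, dst, _rel in p.edges:
        succ[src].add(dst)
    return {n: len(s) for n, s in succ.items()}
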