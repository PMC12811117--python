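"""Typed, directed, property-carrying knowledge graph.

The graph is the 4-tuple (N, E, N_p, E_p): a set of typed nodes with scalar
properties and a set of directed, typed edges with scalar properties.
Direction is semantic (source -> target) and is never symmetrized here;
downstream consumers decide how to treat it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: The closed set of entity types the schema admits.
NODE_TYPES = frozenset({
    "gene",
    "disease",
    "medication",
    "individual",
    "cmr",
    "phenotype",
    "anatomy",
    "biological_process",
    "cellular_component",
    "molecular_function",
    "pathway",
    "air_pollutant",
})

Scalar = str | int | float | bool


def _check_properties(props: Mapping[str, Scalar], owner: str) -> dict[str, Scalar]:
    out: dict[str, Scalar] = {}
    for k, v in props.items():
        if not isinstance(v, (str, int, float, bool)):
            raise ValueError(
                f"property {k!r} of {owner} has non-scalar value of type "
                f"{type(v).__name__}; only string/number/boolean allowed"
            )
        out[str(k)] = v
    return out


@dataclass(frozen=True)
class NodeRecord:
    """A single entity: unique id, type tag, and scalar properties."""

    node_id: str
    node_type: str
    properties: dict[str, Scalar] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_id:
            raise ValueError("node_id must be non-empty")
        if self.node_type not in NODE_TYPES:
            raise ValueError(
                f"unknown node_type {self.node_type!r} for node {self.node_id!r}; "
                f"must be one of {sorted(NODE_TYPES)}"
            )
        object.__setattr__(
            self, "properties", _check_properties(self.properties, f"node {self.node_id!r}")
        )


@dataclass(frozen=True)
class EdgeRecord:
    """A directed, typed edge with scalar properties."""

    source_id: str
    target_id: str
    relation_type: str
    properties: dict[str, Scalar] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.source_id or not self.target_id:
            raise ValueError("edge endpoints must be non-empty ids")
        if not self.relation_type:
            raise ValueError("relation_type must be non-empty")
        object.__setattr__(
            self,
            "properties",
            _check_properties(
                self.properties,
                f"edge ({self.source_id!r} -> {self.target_id!r}, {self.relation_type!r})",
            ),
        )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source_id, self.target_id, self.relation_type)


class KnowledgeGraph:
    """Immutable-by-convention container with referential integrity.

    Nodes are keyed by id; edges by the (source, target, relation) triple.
    Every edge endpoint must name an existing node.
    """

    def __init__(self, nodes: Iterable[NodeRecord], edges: Iterable[EdgeRecord]):
        self._nodes: dict[str, NodeRecord] = {}
        for n in nodes:
            if n.node_id in self._nodes:
                raise ValueError(f"duplicate node_id {n.node_id!r}")
            self._nodes[n.node_id] = n
        self._edges: dict[tuple[str, str, str], EdgeRecord] = {}
        for e in edges:
            if e.source_id not in self._nodes or e.target_id not in self._nodes:
                raise ValueError(
                    f"edge ({e.source_id!r} -> {e.target_id!r}, {e.relation_type!r}) "
                    "references a node absent from the graph"
                )
            if e.key in self._edges:
                logger.warning(
                    "duplicate edge %r collapsed; first-seen properties kept", e.key
                )
                continue
            self._edges[e.key] = e

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self) -> list[NodeRecord]:
        return list(self._nodes.values())

    @property
    def edges(self) -> list[EdgeRecord]:
        return list(self._edges.values())

    @property
    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def node(self, node_id: str) -> NodeRecord:
        return self._nodes[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def has_edge(self, source_id: str, target_id: str, relation_type: str | None = None) -> bool:
        if relation_type is not None:
            return (source_id, target_id, relation_type) in self._edges
        return any(k[0] == source_id and k[1] == target_id for k in self._edges)

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return set(self._edges)

    def directed_pairs(self) -> set[tuple[str, str]]:
        """Distinct (source, target) pairs, relation types merged."""
        return {(s, t) for (s, t, _r) in self._edges}

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __repr__(self) -> str:  # pragma: no cover
        return f"KnowledgeGraph(|N|={self.n_nodes}, |E|={self.n_edges})"


def build_graph(nodes: Iterable[NodeRecord], edges: Iterable[EdgeRecord]) -> KnowledgeGraph:
    """Assemble a graph from node and edge records.

    Exact duplicate (source, target, relation) rows collapse to one edge with
    first-seen properties; an edge naming an absent node or a repeated
    node_id is an error.
    """
    return KnowledgeGraph(nodes, edges)


def remove_node_types(kg: KnowledgeGraph, types: Iterable[str]) -> KnowledgeGraph:
    """Return a new graph without nodes of the given types or their edges."""
    types = set(types)
    unknown = types - NODE_TYPES
    if unknown:
        raise ValueError(f"unknown node type(s): {sorted(unknown)}")
    keep = [n for n in kg.nodes if n.node_type not in types]
    keep_ids = {n.node_id for n in keep}
    edges = [e for e in kg.edges if e.source_id in keep_ids and e.target_id in keep_ids]
    return KnowledgeGraph(keep, edges)


def graph_summary(kg: KnowledgeGraph) -> dict:
    """Per-type node counts and total edge count."""
    counts = {t: 0 for t in sorted(NODE_TYPES)}
    for n in kg.nodes:
        counts[n.node_type] += 1
    return {"node_counts": counts, "n_nodes": kg.n_nodes, "n_edges": kg.n_edges}


def to_networkx(kg: KnowledgeGraph):
    """Directed networkx view (one arc per distinct source->target pair)."""
    import networkx as nx

    g = nx.DiGraph()
    for n in kg.nodes:
        g.add_node(n.node_id, node_type=n.node_type, **n.properties)
    for e in kg.edges:
        g.add_edge(e.source_id, e.target_id)
    return g
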