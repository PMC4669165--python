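"""Core data model: signed directed gene graphs and pathway records.

The universal carrier is :class:`SignedDigraph`, a directed graph whose nodes
are annotated molecular entities and whose edges carry a sign, ``+1`` for
activation and ``-1`` for inhibition.  Parallel edges with opposite signs
between the same ordered node pair are distinct interactions; an edge is
identified by the full ``(source, target, sign)`` triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: Recognised entity classes for pathway nodes.
ENTITY_CLASSES = frozenset(
    {"protein", "complex", "small_molecule", "dna", "rna", "nested_pathway", "other"}
)

#: Entity classes removed (with rewiring) when reducing a pathway graph to genes.
DEFAULT_REMOVABLE_CLASSES = frozenset({"small_molecule", "dna", "rna", "nested_pathway"})

#: Curation groups for pathway records.
GROUPS = ("canonical", "noncanonical", "inhibition", "regulation", "unassigned", "discarded")

ACTIVATION = 1
INHIBITION = -1


class GraphIntegrityError(ValueError):
    """An edge references a node that is not annotated in the graph."""


@dataclass
class EntityNode:
    """One annotated pathway entity.

    Parameters
    ----------
    node_id : str
        Opaque identifier, unique within its graph.
    entity_class : str
        One of :data:`ENTITY_CLASSES`.
    reference_ids : list of (namespace, id)
        External database references, e.g. ``("uniprot", "P35222")``.
    gene_symbols : list of str
        HGNC symbols mapped onto this entity.  Empty before identifier
        mapping or when no reference is mappable; a gene-level node carries
        exactly one symbol.
    display_name : str
        Free-text instance name, used as the node label when no symbol is
        available.
    """

    node_id: str
    entity_class: str = "protein"
    reference_ids: list[tuple[str, str]] = field(default_factory=list)
    gene_symbols: list[str] = field(default_factory=list)
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.node_id:
            raise ValueError("node_id must be non-empty")
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(
                f"unknown entity_class {self.entity_class!r}; expected one of "
                f"{sorted(ENTITY_CLASSES)}"
            )
        self.gene_symbols = [s.strip().upper() for s in self.gene_symbols if s.strip()]

    @property
    def label(self) -> str:
        """Preferred node label: the single symbol, else the display name, else the id."""
        if len(self.gene_symbols) == 1:
            return self.gene_symbols[0]
        return self.display_name or self.node_id


class SignedDigraph:
    """Directed graph with signed edges, backed by a :class:`networkx.MultiDiGraph`.

    Edge multiplicity is restricted to sign: at most one edge per
    ``(source, target, sign)`` triple.  Self-loops are rejected unless
    ``allow_self_loops`` is set; the gene-graph transformations drop any
    self-loop they would otherwise create.
    """

    def __init__(self, allow_self_loops: bool = False) -> None:
        self._g = nx.MultiDiGraph()
        self.allow_self_loops = allow_self_loops

    # -- construction -------------------------------------------------

    def add_node(self, node: EntityNode | str) -> None:
        if isinstance(node, str):
            node = EntityNode(node_id=node, gene_symbols=[node])
        self._g.add_node(node.node_id, entity=node)

    def add_edge(self, source: str, target: str, sign: int) -> None:
        if sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"edge sign must be 1 or -1, got {sign!r}")
        if source == target and not self.allow_self_loops:
            raise ValueError(f"self-loop on {source!r} not permitted")
        for endpoint in (source, target):
            if endpoint not in self._g:
                raise GraphIntegrityError(f"edge endpoint {endpoint!r} is not a node")
        self._g.add_edge(source, target, key=sign)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        nodes: Iterable[EntityNode] | None = None,
    ) -> "SignedDigraph":
        """Build a graph from ``(source, target, sign)`` triples.

        Endpoints without an explicit :class:`EntityNode` annotation become
        single-symbol gene nodes labelled by their id.
        """
        g = cls()
        if nodes is not None:
            for n in nodes:
                g.add_node(n)
        for u, v, s in edges:
            for endpoint in (u, v):
                if endpoint not in g._g:
                    g.add_node(endpoint)
            g.add_edge(u, v, s)
        return g

    def copy(self) -> "SignedDigraph":
        out = SignedDigraph(allow_self_loops=self.allow_self_loops)
        out._g = self._g.copy()
        return out

    # -- inspection ---------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return list(self._g.nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def entity(self, node_id: str) -> EntityNode:
        return self._g.nodes[node_id]["entity"]

    def set_entity(self, node: EntityNode) -> None:
        if node.node_id not in self._g:
            raise KeyError(node.node_id)
        self._g.nodes[node.node_id]["entity"] = node

    def entities(self) -> Iterator[EntityNode]:
        for _, data in self._g.nodes(data=True):
            yield data["entity"]

    def edges(self) -> set[tuple[str, str, int]]:
        """The edge set as ``(source, target, sign)`` triples."""
        return {(u, v, k) for u, v, k in self._g.edges(keys=True)}

    def degree(self, node_id: str) -> int:
        """Total (in + out) incident edge count, parallel signed edges included."""
        return self._g.in_degree(node_id) + self._g.out_degree(node_id)

    def in_edges(self, node_id: str) -> set[tuple[str, str, int]]:
        return {(u, v, k) for u, v, k in self._g.in_edges(node_id, keys=True)}

    def out_edges(self, node_id: str) -> set[tuple[str, str, int]]:
        return {(u, v, k) for u, v, k in self._g.out_edges(node_id, keys=True)}

    def symbols(self) -> set[str]:
        """All HGNC symbols carried by nodes of this graph."""
        out: set[str] = set()
        for e in self.entities():
            out.update(e.gene_symbols)
        return out

    # -- projections --------------------------------------------------

    def to_simple_digraph(self) -> nx.DiGraph:
        """Directed unweighted projection: parallel signed edges collapsed."""
        g = nx.DiGraph()
        g.add_nodes_from(self._g.nodes)
        g.add_edges_from({(u, v) for u, v, _ in self._g.edges(keys=True)})
        return g

    def to_undirected_simple(self) -> nx.Graph:
        """Undirected, unweighted, loop-free simple projection."""
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        g.add_edges_from({(u, v) for u, v, _ in self._g.edges(keys=True) if u != v})
        return g

    def induced_subgraph(self, node_ids: Iterable[str]) -> "SignedDigraph":
        """Subgraph on ``node_ids`` with all edges between them (signs kept)."""
        keep = set(node_ids) & set(self._g.nodes)
        out = SignedDigraph(allow_self_loops=self.allow_self_loops)
        for n in keep:
            out.add_node(self.entity(n))
        for u, v, s in self.edges():
            if u in keep and v in keep:
                out.add_edge(u, v, s)
        return out

    def relabeled(self, mapping: Mapping[str, str]) -> "SignedDigraph":
        """Relabel node ids; ids merged by the mapping union their edges.

        Duplicate triples collapse and self-loops arising from the merge are
        dropped.
        """
        out = SignedDigraph(allow_self_loops=self.allow_self_loops)
        for n in self._g.nodes:
            new_id = mapping.get(n, n)
            if new_id not in out._g:
                out.add_node(replace(self.entity(n), node_id=new_id))
        for u, v, s in self.edges():
            nu, nv = mapping.get(u, u), mapping.get(v, v)
            if nu == nv:
                continue
            out.add_edge(nu, nv, s)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and self.edges() == other.edges()

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SignedDigraph({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class PathwayRecord:
    """One pathway graph with its provenance and curation group."""

    pathway_id: str
    name: str
    source_db: str
    graph: SignedDigraph
    group: str = "unassigned"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
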