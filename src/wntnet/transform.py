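"""Gene-graph transformation rules.

A parsed pathway graph mixes proteins with small molecules, nucleic acids and
nested pathways, and annotates nodes with database references rather than
gene symbols.  The operations here reduce such a graph to a gene-level signed
digraph:

1. :func:`map_identifiers` — convert reference ids to HGNC symbols, falling
   back to the instance display name when nothing maps;
2. :func:`filter_nonmappable_nodes` — remove entities that cannot be matched
   to expression data, preserving connectivity by rewiring around them (the
   sign of a rewired edge is the product of the signs along the bypassed
   path: inhibition of an inhibitor activates);
3. :func:`split_multi_symbol_nodes` / :func:`merge_same_symbol_nodes` —
   enforce a one-to-one correspondence between gene nodes and symbols.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Mapping

from .model import DEFAULT_REMOVABLE_CLASSES, EntityNode, PathwayRecord, SignedDigraph

logger = logging.getLogger(__name__)

__all__ = [
    "select_pathways_by_keywords",
    "map_identifiers",
    "filter_nonmappable_nodes",
    "split_multi_symbol_nodes",
    "merge_same_symbol_nodes",
    "to_gene_graph",
]


def select_pathways_by_keywords(
    records: list[PathwayRecord], keywords: Iterable[str]
) -> list[PathwayRecord]:
    """Select pathways whose name or member annotations contain a keyword.

    Matching is a case-insensitive substring test against the pathway name
    and against every member node's symbols and display name.  Input order is
    preserved.
    """
    kws = [k.lower() for k in keywords]
    if not kws:
        raise ValueError("keywords must be non-empty")
    if any(not k for k in kws):
        raise ValueError("empty keyword string")

    def matches(rec: PathwayRecord) -> bool:
        haystacks = [rec.name.lower()]
        for ent in rec.graph.entities():
            haystacks.append(ent.display_name.lower())
            haystacks.extend(s.lower() for s in ent.gene_symbols)
        return any(any(kw in h for h in haystacks) for kw in kws)

    return [rec for rec in records if matches(rec)]


def map_identifiers(
    graph: SignedDigraph, id_map: Mapping[tuple[str, str], str]
) -> SignedDigraph:
    """Annotate every node with the HGNC symbols of its mapped references.

    Symbols are deduplicated with stable order.  Nodes with no mappable
    reference keep an empty symbol list; their display name remains the
    label.  Unmapped references are not an error.
    """
    out = graph.copy()
    for ent in graph.entities():
        symbols: list[str] = []
        for ref in ent.reference_ids:
            sym = id_map.get(ref)
            if sym and sym not in symbols:
                symbols.append(sym)
        out.set_entity(replace(ent, gene_symbols=symbols))
    return out


def _removable(ent: EntityNode, removable_classes: frozenset[str]) -> bool:
    if ent.entity_class in removable_classes:
        return True
    return not ent.gene_symbols and not ent.display_name


def filter_nonmappable_nodes(
    graph: SignedDigraph,
    removable_classes: Iterable[str] = DEFAULT_REMOVABLE_CLASSES,
) -> SignedDigraph:
    """Remove non-gene entities, rewiring around them to preserve connectivity.

    A kept pair ``(u, w)`` receives an edge of sign *s* exactly when some
    directed path from *u* to *w* exists whose interior nodes are all
    removable and whose edge signs multiply to *s*.  The computation walks
    sign-annotated reachability states through the removable subgraph, so the
    result is independent of any removal order and chains of removable nodes
    are traversed to fixpoint.  Self-loops created by rewiring are dropped
    and duplicate triples collapse.

    Nodes of a removable entity class are removed, as are nodes with neither
    a gene symbol nor a display name (nothing to match expression data on).
    """
    removable_classes = frozenset(removable_classes)
    removable = {e.node_id for e in graph.entities() if _removable(e, removable_classes)}
    kept = [n for n in graph.node_ids if n not in removable]

    out = SignedDigraph(allow_self_loops=graph.allow_self_loops)
    for n in kept:
        out.add_node(graph.entity(n))

    for u in kept:
        # states: (removable node, accumulated sign product from u)
        seen: set[tuple[str, int]] = set()
        stack: list[tuple[str, int]] = []
        for _, x, s in graph.out_edges(u):
            if x in removable:
                if (x, s) not in seen:
                    seen.add((x, s))
                    stack.append((x, s))
            elif x != u:
                out.add_edge(u, x, s)
        while stack:
            x, s = stack.pop()
            for _, y, t in graph.out_edges(x):
                ns = s * t
                if y in removable:
                    if (y, ns) not in seen:
                        seen.add((y, ns))
                        stack.append((y, ns))
                elif y != u:
                    out.add_edge(u, y, ns)

    if out.n_nodes == 0 and graph.n_nodes > 0:
        logger.warning("filtering removed every node; returning an empty graph")
    return out


def split_multi_symbol_nodes(graph: SignedDigraph) -> SignedDigraph:
    """Split every node carrying k > 1 symbols into k single-symbol nodes.

    Each replacement inherits all incident edges of the original, with the
    same directions and signs.
    """
    replacements: dict[str, list[EntityNode]] = {}
    for ent in graph.entities():
        if len(ent.gene_symbols) > 1:
            replacements[ent.node_id] = [
                replace(ent, node_id=f"{ent.node_id}::{sym}", gene_symbols=[sym])
                for sym in ent.gene_symbols
            ]
        else:
            replacements[ent.node_id] = [ent]

    out = SignedDigraph(allow_self_loops=graph.allow_self_loops)
    for ents in replacements.values():
        for ent in ents:
            out.add_node(ent)
    for u, v, s in graph.edges():
        for eu in replacements[u]:
            for ev in replacements[v]:
                out.add_edge(eu.node_id, ev.node_id, s)
    return out


def merge_same_symbol_nodes(graph: SignedDigraph) -> SignedDigraph:
    """Merge nodes that share a label and canonicalise node ids to labels.

    Gene nodes (exactly one symbol) merge by symbol; unmapped nodes merge by
    display name.  The merged node's edges are the union of its constituents'
    edges with endpoints relabeled; duplicate triples collapse and self-loops
    arising from the merge are dropped.
    """
    mapping: dict[str, str] = {}
    for ent in graph.entities():
        if len(ent.gene_symbols) > 1:
            raise ValueError(
                f"node {ent.node_id!r} carries {len(ent.gene_symbols)} symbols; "
                "apply split_multi_symbol_nodes first"
            )
        mapping[ent.node_id] = ent.label
    return graph.relabeled(mapping)


def to_gene_graph(
    graph: SignedDigraph,
    id_map: Mapping[tuple[str, str], str],
    removable_classes: Iterable[str] = DEFAULT_REMOVABLE_CLASSES,
) -> SignedDigraph:
    """Full reduction: map ids, filter non-gene entities, split, merge."""
    g = map_identifiers(graph, id_map)
    g = filter_nonmappable_nodes(g, removable_classes)
    g = split_multi_symbol_nodes(g)
    return merge_same_symbol_nodes(g)
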