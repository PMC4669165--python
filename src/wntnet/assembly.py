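"""Stratify pathway records into curation groups and merge them into networks.

Group membership is expert curation supplied as an explicit
``pathway_id -> group`` assignment; it is never derived automatically.
Merging a group concatenates the member pathways' interaction triples,
removes duplicates, and keeps only nodes that carry at least one
interaction.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import networkx as nx

from .model import GROUPS, PathwayRecord, SignedDigraph

logger = logging.getLogger(__name__)

__all__ = [
    "assign_groups",
    "split_record_by_components",
    "merge_group",
    "build_networks",
]


def assign_groups(
    records: list[PathwayRecord], assignment: dict[str, str]
) -> list[PathwayRecord]:
    """Set each record's group from the assignment mapping.

    Records not mentioned in the assignment are discarded (too general or
    unspecific to classify).

    Raises
    ------
    KeyError
        If the assignment names a pathway_id absent from ``records``.
    """
    known = {rec.pathway_id for rec in records}
    unknown = sorted(set(assignment) - known)
    if unknown:
        raise KeyError(f"assignment names unknown pathway_id(s): {', '.join(unknown)}")
    for group in assignment.values():
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    return [
        replace(rec, group=assignment.get(rec.pathway_id, "discarded")) for rec in records
    ]


def split_record_by_components(
    record: PathwayRecord, component_groups: dict[str, str]
) -> list[PathwayRecord]:
    """Split a mixed pathway into per-component records with mapped groups.

    Each weakly connected component containing a representative node becomes
    its own record carrying that component's induced subgraph and the
    representative's mapped group.  Components without a representative are
    not emitted (discarded).

    Raises
    ------
    ValueError
        If two representatives fall in the same component (ambiguous group).
    """
    undirected = record.graph.to_undirected_simple()
    components = [set(c) for c in nx.connected_components(undirected)]
    out: list[PathwayRecord] = []
    for idx, comp in enumerate(sorted(components, key=min)):
        reps = sorted(set(component_groups) & comp)
        if len(reps) > 1:
            raise ValueError(
                f"representatives {reps} lie in the same connected component of "
                f"{record.pathway_id!r}; group assignment is ambiguous"
            )
        if not reps:
            continue
        out.append(
            PathwayRecord(
                pathway_id=f"{record.pathway_id}#{idx}",
                name=record.name,
                source_db=record.source_db,
                graph=record.graph.induced_subgraph(comp),
                group=component_groups[reps[0]],
            )
        )
    return out


def merge_group(records: list[PathwayRecord], group: str) -> SignedDigraph:
    """Union the interaction triples of all records in one group.

    The merged network contains only nodes incident to at least one edge,
    and is independent of record order (set-union semantics over
    ``(source, target, sign)`` triples).
    """
    members = [rec for rec in records if rec.group == group]
    if not members:
        raise ValueError(f"no records carry group {group!r}")
    triples: set[tuple[str, str, int]] = set()
    entities = {}
    for rec in members:
        triples |= rec.graph.edges()
        for ent in rec.graph.entities():
            entities.setdefault(ent.node_id, ent)
    merged = SignedDigraph()
    for u, v, _ in triples:
        for endpoint in (u, v):
            if endpoint not in merged:
                merged.add_node(entities[endpoint])
    for u, v, s in triples:
        merged.add_edge(u, v, s)
    return merged


def build_networks(records: list[PathwayRecord]) -> dict[str, SignedDigraph]:
    """Merge each non-discarded group present among the records.

    Sizes are reported in the run log, one line per network.
    """
    present = [g for g in GROUPS if g not in ("discarded", "unassigned")]
    networks: dict[str, SignedDigraph] = {}
    for group in present:
        if any(rec.group == group for rec in records):
            net = merge_group(records, group)
            networks[group] = net
            logger.info("network %s: %d nodes, %d edges", group, net.n_nodes, net.n_edges)
    return networks
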