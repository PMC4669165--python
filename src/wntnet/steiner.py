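"""Steiner-tree extraction of differentially regulated network modules.

DEG-matched network nodes become *terminals*; a Steiner tree approximated by
the Kou–Markowsky–Berman (KMB) heuristic connects them on the undirected,
unweighted (hop-metric) projection, introducing *Steiner nodes* where needed
for connectivity.  The module is then the source network's induced signed
subgraph on the tree's node set — all directed signed edges between those
nodes, not just the tree edges — annotated with each terminal's log
fold-change.

The KMB heuristic: build the metric closure over terminals (hop distances),
take its minimum spanning tree, expand every closure edge back into a
shortest path, take a spanning tree of the expansion, and prune non-terminal
leaves.  Its tree has at most twice the optimal number of edges.  All ties
(shortest paths, MST edge order) are broken lexicographically, so the result
is deterministic.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .enrichment import GeneSet
from .io import read_sif, write_sif
from .model import SignedDigraph

logger = logging.getLogger(__name__)

__all__ = [
    "SteinerModule",
    "map_terminals",
    "steiner_tree",
    "induce_module",
    "extract_module",
    "annotate_for_export",
    "write_module",
    "read_module",
]


@dataclass
class SteinerModule:
    """A differentially regulated module extracted from a signed network."""

    graph: SignedDigraph
    node_roles: dict[str, str]  # node_id -> "terminal" | "steiner"
    node_log_fc: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for node in self.graph.node_ids:
            role = self.node_roles.get(node)
            if role not in ("terminal", "steiner"):
                raise ValueError(f"node {node!r} has no valid role (got {role!r})")
            if role == "terminal" and node not in self.node_log_fc:
                raise ValueError(f"terminal {node!r} lacks a log fold-change")

    @property
    def terminals(self) -> set[str]:
        return {n for n, r in self.node_roles.items() if r == "terminal"}

    @property
    def steiner_nodes(self) -> set[str]:
        return {n for n, r in self.node_roles.items() if r == "steiner"}


def map_terminals(
    network: SignedDigraph, up: GeneSet, down: GeneSet
) -> tuple[set[str], set[str]]:
    """Match DEG symbols to network nodes and restrict to one component.

    Returns ``(terminals, dropped)``: terminal node ids inside the largest
    connected component of the undirected projection, and the DEG symbols
    that are absent from the network or fall outside that component.
    """
    if up.genes & down.genes:
        raise ValueError("up- and down-regulated sets must be disjoint")
    symbols = up.genes | down.genes
    by_label = {network.entity(n).label: n for n in network.node_ids}
    matched = {by_label[s] for s in symbols if s in by_label}
    if not matched:
        raise ValueError("no DEGs map to network")
    undirected = network.to_undirected_simple()
    giant = min(nx.connected_components(undirected), key=lambda c: (-len(c), min(c)))
    terminals = matched & set(giant)
    if not terminals:
        raise ValueError("no DEGs map to network (none in the largest component)")
    kept_symbols = {network.entity(n).label for n in terminals}
    dropped = symbols - kept_symbols
    if dropped:
        logger.info("%d DEG symbol(s) dropped (unmapped or outside component)", len(dropped))
    return terminals, dropped


def _bfs_tree(adj: dict[str, list[str]], source: str) -> tuple[dict[str, int], dict[str, str]]:
    """BFS distances and predecessors with sorted-adjacency tie-breaking."""
    dist = {source: 0}
    parent: dict[str, str] = {}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parent[v] = u
                queue.append(v)
    return dist, parent


def _path(parent: dict[str, str], source: str, target: str) -> list[str]:
    path = [target]
    while path[-1] != source:
        path.append(parent[path[-1]])
    return path[::-1]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def steiner_tree(network: SignedDigraph, terminals: set[str]) -> nx.Graph:
    """KMB approximate Steiner tree on the undirected hop-metric projection.

    Returns an undirected tree (``networkx.Graph``) containing every
    terminal; non-terminal tree nodes are the Steiner nodes.  Deterministic:
    shortest paths come from BFS over sorted adjacency and both MST stages
    use lexicographically ordered Kruskal.

    Raises
    ------
    ValueError
        If the terminals do not lie in a single connected component.
    """
    if not terminals:
        raise ValueError("terminals must be non-empty")
    undirected = network.to_undirected_simple()
    missing = terminals - set(undirected.nodes)
    if missing:
        raise ValueError(f"terminal(s) not in network: {sorted(missing)}")
    terms = sorted(terminals)
    adj = {u: sorted(undirected.neighbors(u)) for u in undirected.nodes}

    if len(terms) == 1:
        tree = nx.Graph()
        tree.add_node(terms[0])
        return tree

    # metric closure restricted to terminals
    dist: dict[str, dict[str, int]] = {}
    parent: dict[str, dict[str, str]] = {}
    for t in terms:
        dist[t], parent[t] = _bfs_tree(adj, t)
    closure_edges = []
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if b not in dist[a]:
                raise ValueError(
                    "terminals span multiple connected components; restrict them first"
                )
            closure_edges.append((dist[a][b], a, b))
    closure_edges.sort()

    # MST of the closure (Kruskal), then expand closure edges to host paths
    uf = _UnionFind()
    expansion = nx.Graph()
    for d, a, b in closure_edges:
        if uf.union(a, b):
            nx.add_path(expansion, _path(parent[a], a, b))

    # spanning tree of the expansion (unit weights, lexicographic Kruskal)
    uf2 = _UnionFind()
    tree = nx.Graph()
    tree.add_nodes_from(expansion.nodes)
    for a, b in sorted(tuple(sorted(e)) for e in expansion.edges):
        if uf2.union(a, b):
            tree.add_edge(a, b)

    # prune non-terminal leaves
    leaves = [n for n in tree.nodes if tree.degree(n) == 1 and n not in terminals]
    while leaves:
        tree.remove_nodes_from(leaves)
        leaves = [n for n in tree.nodes if tree.degree(n) == 1 and n not in terminals]
    return tree


def induce_module(
    network: SignedDigraph,
    tree_nodes: set[str],
    roles: dict[str, str],
    de_table: pd.DataFrame | None = None,
    provenance: str = "",
) -> SteinerModule:
    """Induce the signed module on the tree's node set.

    The module graph carries *all* directed signed edges of the source
    network between ``tree_nodes`` — induced-subgraph semantics, not just
    the tree edges.  Terminal nodes receive their log fold-change from
    ``de_table`` (matched by node label).
    """
    unknown = tree_nodes - set(network.node_ids)
    if unknown:
        raise ValueError(f"tree node(s) not in network: {sorted(unknown)}")
    graph = network.induced_subgraph(tree_nodes)
    log_fc: dict[str, float] = {}
    if de_table is not None:
        lookup = dict(zip(de_table["gene"], de_table["log_fc"]))
        for node in tree_nodes:
            if roles.get(node) == "terminal":
                label = network.entity(node).label
                if label in lookup:
                    log_fc[node] = float(lookup[label])
    return SteinerModule(
        graph=graph,
        node_roles={n: roles[n] for n in tree_nodes},
        node_log_fc=log_fc,
        provenance=provenance,
    )


def extract_module(
    network: SignedDigraph,
    up: GeneSet,
    down: GeneSet,
    de_table: pd.DataFrame,
    provenance: str = "",
) -> SteinerModule:
    """Full module pipeline: map terminals, approximate the tree, induce."""
    terminals, _ = map_terminals(network, up, down)
    tree = steiner_tree(network, terminals)
    roles = {n: ("terminal" if n in terminals else "steiner") for n in tree.nodes}
    return induce_module(network, set(tree.nodes), roles, de_table, provenance)


def annotate_for_export(module: SteinerModule, cap: float = 3.0) -> pd.DataFrame:
    """Node attribute table with fold-changes clamped for display.

    ``log_fc_display`` is the raw value clamped to ``[-cap, +cap]`` (colour
    scales saturate beyond that); the raw value is preserved alongside.
    Steiner nodes export an empty display value.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    rows = []
    for node in sorted(module.graph.node_ids):
        role = module.node_roles[node]
        if role == "terminal" and node in module.node_log_fc:
            raw = module.node_log_fc[node]
            display = min(max(raw, -cap), cap)
        else:
            raw, display = float("nan"), float("nan")
        rows.append((node, role, raw, display))
    return pd.DataFrame(rows, columns=["node", "role", "log_fc_raw", "log_fc_display"])


def write_module(module: SteinerModule, prefix) -> tuple[str, str]:
    """Write ``<prefix>.edges.tsv`` (SIF) and ``<prefix>.nodes.tsv``."""
    edges_path = f"{prefix}.edges.tsv"
    nodes_path = f"{prefix}.nodes.tsv"
    write_sif(module.graph, edges_path)
    annotate_for_export(module).to_csv(nodes_path, sep="\t", index=False)
    return edges_path, nodes_path


def read_module(edges_path, nodes_path, provenance: str = "") -> SteinerModule:
    """Read a module export back (raw fold-changes, roles, signed edges)."""
    graph = read_sif(edges_path)
    nodes = pd.read_csv(nodes_path, sep="\t")
    roles = dict(zip(nodes["node"], nodes["role"]))
    log_fc = {
        row.node: float(row.log_fc_raw)
        for row in nodes.itertuples(index=False)
        if row.role == "terminal" and pd.notna(row.log_fc_raw)
    }
    for node in nodes["node"]:
        if node not in graph:
            graph.add_node(str(node))
    return SteinerModule(graph=graph, node_roles=roles, node_log_fc=log_fc, provenance=provenance)
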