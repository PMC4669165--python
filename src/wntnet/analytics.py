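"""Centralities, key nodes, community structure, and gene subnetworks.

Degree counts all incident signed edges of a node.  Betweenness is computed
on the directed unweighted simple projection (parallel signed edges
collapsed), with fractional credit when several shortest paths tie.  Key
nodes are the overlap of the top-k degree and top-k betweenness lists.
Community detection uses greedy (Clauset–Newman–Moore) modularity
maximisation on the undirected simple projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .model import SignedDigraph

logger = logging.getLogger(__name__)

__all__ = ["Partition", "centralities", "key_nodes", "detect_communities", "extract_gene_subnetwork"]


@dataclass
class Partition:
    """A node partition with its modularity score.

    ``membership`` maps every node to a community index; indices are
    contiguous from 0, ordered by each community's smallest node label.
    """

    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, idx in self.membership.items():
            out.setdefault(idx, set()).add(node)
        return [out[i] for i in sorted(out)]


def centralities(graph: SignedDigraph) -> pd.DataFrame:
    """Per-node degree and betweenness centrality.

    Returns a DataFrame indexed by node with columns ``degree`` (total
    incident signed edges) and ``betweenness`` (unnormalised, directed).
    """
    if graph.n_nodes == 0:
        raise ValueError("centralities of an empty graph are undefined")
    simple = graph.to_simple_digraph()
    bc = nx.betweenness_centrality(simple, normalized=False)
    nodes = sorted(graph.node_ids)
    return pd.DataFrame(
        {
            "degree": [graph.degree(n) for n in nodes],
            "betweenness": [bc[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _top_k_with_ties(scores: pd.Series, k: int) -> set[str]:
    """Nodes scoring at least as high as the k-th ranked score."""
    ordered = scores.sort_values(ascending=False, kind="stable")
    if len(ordered) <= k:
        return set(ordered.index)
    cutoff = ordered.iloc[k - 1]
    return set(ordered[ordered >= cutoff].index)


def key_nodes(graph: SignedDigraph, k: int = 15) -> set[str]:
    """Nodes in both the top-k-by-degree and top-k-by-betweenness lists.

    Ties at rank k are all included, so either list may exceed k.  A graph
    with fewer than k nodes uses every node for both lists (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table = centralities(graph)
    if graph.n_nodes < k:
        logger.info("graph has %d < k=%d nodes; every node enters both lists", graph.n_nodes, k)
    return _top_k_with_ties(table["degree"], k) & _top_k_with_ties(table["betweenness"], k)


def detect_communities(graph: SignedDigraph) -> Partition:
    """Greedy modularity (CNM) communities of the undirected simple projection.

    The partition with maximal modularity along the agglomerative merge path
    is returned.  Disconnected graphs are allowed; singleton components form
    their own communities.  Deterministic for a given graph.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot partition an empty graph")
    undirected = graph.to_undirected_simple()
    if undirected.number_of_edges() == 0:
        communities: list[set[str]] = [{n} for n in sorted(undirected.nodes)]
        q = 0.0
    else:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(undirected)]
        q = nx.community.modularity(undirected, communities)
    communities.sort(key=min)
    membership = {node: idx for idx, comm in enumerate(communities) for node in comm}
    return Partition(membership=membership, modularity=q)


def extract_gene_subnetwork(
    networks: Mapping[str, SignedDigraph], genes: Iterable[str]
) -> tuple[SignedDigraph, int]:
    """Unified subnetwork of the listed genes across all networks.

    Takes the union over networks of edges whose *both* endpoints are listed
    genes (duplicate triples collapse) and returns it together with the
    number of listed genes connected by at least one edge.  Genes absent
    from every network simply do not appear.
    """
    gene_set = {g.strip().upper() for g in genes}
    if not gene_set:
        raise ValueError("gene list must be non-empty")
    triples: set[tuple[str, str, int]] = set()
    for net in networks.values():
        triples |= {(u, v, s) for u, v, s in net.edges() if u in gene_set and v in gene_set}
    sub = SignedDigraph.from_edges(sorted(triples))
    n_connected = sum(1 for g in gene_set if g in sub and sub.degree(g) >= 1)
    return sub, n_connected
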