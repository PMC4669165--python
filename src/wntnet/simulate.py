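"""Synthetic pathway collections and two-group expression data.

Every pipeline stage is testable without downloads: the generator emulates
parsed pathway-database graphs (including the awkward features of real
exports — non-gene entities such as metabolites and nested pathways, and
nodes annotated with several gene symbols) over a shared gene universe, and
two-condition log-intensity expression data with differential expression
planted in chosen genes.

The expression model is deliberately simple: independent Gaussian
log-intensities with a mean shift of ``effect`` for planted genes, analysed
by per-gene two-sample t-tests with Bonferroni adjustment.  The pipeline
consumes DE tables agnostically, so this stand-in does not constrain use
with moderated-statistics tables from real platforms.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet, bonferroni
from .model import EntityNode, GROUPS, PathwayRecord, SignedDigraph

__all__ = [
    "universe_symbols",
    "synthetic_id_map",
    "simulate_pathway_collection",
    "round_robin_assignment",
    "simulate_expression",
    "plant_connected_terminals",
]

_REMOVABLE = ("small_molecule", "dna", "rna", "nested_pathway")


def universe_symbols(genes: int) -> list[str]:
    """The shared synthetic gene universe: symbols ``G0001`` … ``G{genes}``."""
    return [f"G{i:04d}" for i in range(1, genes + 1)]


def synthetic_id_map(genes: int) -> dict[tuple[str, str], str]:
    """Entrez and UniProt references for the synthetic universe."""
    out: dict[tuple[str, str], str] = {}
    for i, sym in enumerate(universe_symbols(genes), start=1):
        out[("entrez", str(10000 + i))] = sym
        out[("uniprot", f"P{i:05d}")] = sym
    return out


def _gene_node(pid: str, idx: int, symbols: list[str]) -> EntityNode:
    refs = []
    for sym in symbols:
        i = int(sym[1:])
        refs.append(("entrez", str(10000 + i)))
    return EntityNode(
        node_id=f"{pid}_n{idx}",
        entity_class="protein",
        reference_ids=refs,
        gene_symbols=[],
        display_name=f"{'/'.join(s.lower() for s in symbols)} protein",
    )


def simulate_pathway_collection(
    n_pathways: int,
    genes: int,
    p_nongene: float = 0.2,
    p_multisymbol: float = 0.1,
    seed: int = 0,
    mean_size: int = 25,
) -> list[PathwayRecord]:
    """Simulate a collection of connected signed pathway graphs.

    Pathways draw their members from a shared universe of ``genes`` symbols,
    so membership overlaps between pathways.  Each gene node carries
    reference ids (resolvable via :func:`synthetic_id_map`) but no symbols
    yet, emulating an unmapped parse.  With probability ``p_multisymbol`` a
    node is annotated with two symbols; each edge is, with probability
    ``p_nongene``, routed through an intermediate non-gene entity
    (metabolite, nucleic acid, or nested pathway).  Deterministic given
    ``seed``.
    """
    if n_pathways < 1 or genes < 3:
        raise ValueError("need at least one pathway over at least three genes")
    for name, p in (("p_nongene", p_nongene), ("p_multisymbol", p_multisymbol)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    universe = universe_symbols(genes)
    records: list[PathwayRecord] = []
    for p_idx in range(1, n_pathways + 1):
        pid = f"pw{p_idx:03d}"
        size = int(np.clip(rng.poisson(mean_size), 5, max(5, genes)))
        members = list(rng.choice(universe, size=size, replace=False))

        # assign symbols to nodes; some nodes carry two symbols
        node_symbols: list[list[str]] = []
        for sym in members:
            if rng.random() < p_multisymbol:
                extra = universe[rng.integers(len(universe))]
                if extra != sym:
                    node_symbols.append([sym, extra])
                    continue
            node_symbols.append([sym])

        graph = SignedDigraph()
        nodes = [_gene_node(pid, i, syms) for i, syms in enumerate(node_symbols)]
        for node in nodes:
            graph.add_node(node)
        ids = [n.node_id for n in nodes]

        # random spanning tree for connectivity, then extra edges
        edges: set[tuple[str, str]] = set()
        order = list(rng.permutation(len(ids)))
        for pos in range(1, len(order)):
            a = ids[order[rng.integers(pos)]]
            b = ids[order[pos]]
            edges.add((a, b) if rng.random() < 0.5 else (b, a))
        n_extra = int(1.5 * len(ids))
        for _ in range(n_extra):
            i, j = rng.integers(len(ids)), rng.integers(len(ids))
            if i != j:
                edges.add((ids[i], ids[j]))

        n_nongene = 0
        for u, v in sorted(edges):
            sign = 1 if rng.random() < 0.75 else -1
            if rng.random() < p_nongene:
                n_nongene += 1
                mid = EntityNode(
                    node_id=f"{pid}_x{n_nongene}",
                    entity_class=_REMOVABLE[rng.integers(len(_REMOVABLE))],
                    display_name=f"intermediate {n_nongene}",
                )
                graph.add_node(mid)
                mid_sign = 1 if rng.random() < 0.75 else -1
                graph.add_edge(u, mid.node_id, sign)
                graph.add_edge(mid.node_id, v, mid_sign)
            else:
                graph.add_edge(u, v, sign)
        if graph.n_edges == 0:
            raise ValueError(f"parameters produced an empty pathway graph ({pid})")
        records.append(
            PathwayRecord(
                pathway_id=pid,
                name=f"synthetic signaling pathway {p_idx}",
                source_db="synthetic",
                graph=graph,
            )
        )
    return records


def round_robin_assignment(
    records: list[PathwayRecord], groups: tuple[str, ...] = GROUPS[:4]
) -> dict[str, str]:
    """Cycle pathway ids through the four curation groups (synthetic curation)."""
    return {rec.pathway_id: groups[i % len(groups)] for i, rec in enumerate(records)}


def simulate_expression(
    network: SignedDigraph,
    planted: GeneSet,
    effect: float = 2.0,
    sigma: float = 0.5,
    n_per_group: int = 3,
    n_background_genes: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group log-intensity expression with planted differential genes.

    Genes are the network's node labels plus ``n_background_genes``
    off-network genes.  Per gene, both groups share a baseline mean
    (N(7, 1)); planted genes gain ``effect`` in group B.  Independent
    Gaussian noise with standard deviation ``sigma`` is added, per-gene
    Welch-free two-sample t-tests (equal variances hold by construction)
    give p-values, and Bonferroni adjustment over all genes yields the DE
    table (``log_fc`` = group-B minus group-A mean on the log2 scale).
    Deterministic given ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("need at least two samples per group")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    labels = sorted({network.entity(n).label for n in network.node_ids})
    missing = planted.genes - set(labels)
    if missing:
        raise ValueError(f"planted genes not in network: {sorted(missing)[:5]}")
    all_genes = labels + [f"BG{i:04d}" for i in range(1, n_background_genes + 1)]

    rng = np.random.default_rng(seed)
    n_genes = len(all_genes)
    baseline = rng.normal(7.0, 1.0, size=n_genes)
    shift = np.array([effect if g in planted.genes else 0.0 for g in all_genes])
    a = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_per_group))
    b = (baseline + shift)[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_per_group))

    expr = pd.DataFrame(
        np.hstack([a, b]),
        index=pd.Index(all_genes, name="gene"),
        columns=[f"A{i+1}" for i in range(n_per_group)] + [f"B{i+1}" for i in range(n_per_group)],
    )
    t_res = stats.ttest_ind(b, a, axis=1)
    de = pd.DataFrame(
        {
            "gene": all_genes,
            "log_fc": b.mean(axis=1) - a.mean(axis=1),
            "p_value": t_res.pvalue,
        }
    )
    de["adj_p"] = bonferroni(de["p_value"])
    return expr, de


def plant_connected_terminals(network: SignedDigraph, n_terminals: int, seed: int = 0) -> GeneSet:
    """Sample a mutually reachable terminal set from one network region.

    Performs a breadth-first sweep from a random start node of the largest
    connected component (undirected projection), collects a neighbourhood of
    about three times the requested size, and samples ``n_terminals`` nodes
    from it, so the planted genes lie in one compact, mutually reachable
    region (typically leaving room for connecting Steiner nodes between
    them).  Deterministic given ``seed``.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    undirected = network.to_undirected_simple()
    giant = sorted(min(nx.connected_components(undirected), key=lambda c: (-len(c), min(c))))
    if n_terminals > len(giant):
        raise ValueError(
            f"n_terminals={n_terminals} exceeds largest component size {len(giant)}"
        )
    rng = np.random.default_rng(seed)
    start = giant[rng.integers(len(giant))]
    neighbourhood_size = min(3 * n_terminals, len(giant))
    seen = {start}
    queue = deque([start])
    neighbourhood: list[str] = []
    while queue and len(neighbourhood) < neighbourhood_size:
        u = queue.popleft()
        neighbourhood.append(u)
        for v in sorted(undirected.neighbors(u)):
            if v not in seen:
                seen.add(v)
                queue.append(v)
    picked = list(rng.choice(neighbourhood, size=n_terminals, replace=False))
    symbols = {network.entity(n).label for n in picked}
    return GeneSet("planted", frozenset(symbols))
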