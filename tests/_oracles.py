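"""Independent brute-force oracles used to check the implementation.

Everything here deliberately avoids the code paths (and, where practical,
the libraries) it is used to verify: shortest paths are enumerated by DFS,
Steiner optima by subset enumeration, rank-sum p-values by combinatorial
enumeration, hypergeometric tails by binomial coefficients, and signed
reachability by boolean matrix closure.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np


def brute_betweenness(digraph) -> dict:
    """Unnormalised directed betweenness by explicit shortest-path enumeration."""
    nodes = list(digraph.nodes)
    adj = {u: sorted(digraph.successors(u)) for u in nodes}
    score = dict.fromkeys(nodes, 0.0)

    def all_paths_upto(s, t, cutoff):
        stack = [(s, [s])]
        while stack:
            u, path = stack.pop()
            if u == t:
                yield path
                continue
            if len(path) > cutoff:
                continue
            for v in adj[u]:
                if v not in path:
                    stack.append((v, path + [v]))

    for s in nodes:
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t in nodes:
            if t == s or t not in dist:
                continue
            shortest = [p for p in all_paths_upto(s, t, dist[t]) if len(p) - 1 == dist[t]]
            for path in shortest:
                for interior in path[1:-1]:
                    score[interior] += 1.0 / len(shortest)
    return score


def optimal_steiner_edge_count(graph, terminals) -> int:
    """Minimum edge count of a Steiner tree by subset enumeration (unit weights).

    Equals ``min |S| - 1`` over node sets S containing the terminals whose
    induced subgraph is connected.
    """
    import networkx as nx

    nodes = [n for n in graph.nodes if n not in terminals]
    terminals = set(terminals)
    best = None
    for r in range(len(nodes) + 1):
        for extra in itertools.combinations(nodes, r):
            s = terminals | set(extra)
            sub = graph.subgraph(s)
            if nx.is_connected(sub):
                best = len(s) - 1
                break
        if best is not None:
            break
    if best is None:
        raise ValueError("terminals not connectable")
    return best


def hypergeom_upper_tail(n_universe: int, n_set: int, n_draws: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeom, via binomial coefficients."""
    total = math.comb(n_universe, n_draws)
    acc = 0
    for i in range(observed, min(n_set, n_draws) + 1):
        if n_draws - i > n_universe - n_set:
            continue
        acc += math.comb(n_set, i) * math.comb(n_universe - n_set, n_draws - i)
    return acc / total


def exact_rank_sum_p(n_total: int, in_ranks) -> float:
    """One-sided P(rank sum <= observed) by full enumeration of placements."""
    in_ranks = sorted(in_ranks)
    k = len(in_ranks)
    observed = sum(in_ranks)
    count = total = 0
    for combo in itertools.combinations(range(1, n_total + 1), k):
        total += 1
        if sum(combo) <= observed:
            count += 1
    return count / total


def signed_reachability(graph, removable) -> set:
    """Kept-pair signed reachability via boolean matrix closure.

    Returns the set of ``(u, w, sign)`` with u, w kept, u != w, such that a
    directed walk from u to w exists with all interior nodes removable and
    edge-sign product ``sign``.  States are (node, parity) and closure is
    computed by repeated boolean matrix multiplication.
    """
    nodes = sorted(graph.node_ids)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    # state ordering: node i with positive parity -> 2i, negative -> 2i+1
    step = np.zeros((2 * n, 2 * n), dtype=bool)
    for u, v, s in graph.edges():
        for parity in (0, 1):
            out_parity = parity if s == 1 else 1 - parity
            step[2 * idx[u] + parity, 2 * idx[v] + out_parity] = True

    # single-step arrival; extend only through removable intermediates
    removable_mask = np.zeros(2 * n, dtype=bool)
    for r in removable:
        removable_mask[2 * idx[r]] = removable_mask[2 * idx[r] + 1] = True
    reach = step.copy()
    for _ in range(2 * n):
        extended = reach | ((reach & removable_mask[None, :]) @ step)
        if (extended == reach).all():
            break
        reach = extended

    kept = [n_ for n_ in nodes if n_ not in removable]
    out = set()
    for u in kept:
        for w in kept:
            if u == w:
                continue
            if reach[2 * idx[u], 2 * idx[w]]:
                out.add((u, w, 1))
            if reach[2 * idx[u], 2 * idx[w] + 1]:
                out.add((u, w, -1))
    return out


def set_partitions(items):
    """All partitions of a list (restricted growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def random_signed_digraph(rng, n_nodes: int, p_edge: float, p_neg: float = 0.3):
    """A random SignedDigraph over string node ids n00..; may be disconnected."""
    from wntnet.model import SignedDigraph

    ids = [f"n{i:02d}" for i in range(n_nodes)]
    g = SignedDigraph()
    for i in ids:
        g.add_node(i)
    for u in ids:
        for v in ids:
            if u != v and rng.random() < p_edge:
                sign = -1 if rng.random() < p_neg else 1
                g.add_edge(u, v, sign)
    return g
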