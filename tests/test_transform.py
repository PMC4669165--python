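import numpy as np
import pytest

from _oracles import random_signed_digraph, signed_reachability
from wntnet.model import EntityNode, PathwayRecord, SignedDigraph
from wntnet.transform import (
    filter_nonmappable_nodes,
    map_identifiers,
    merge_same_symbol_nodes,
    select_pathways_by_keywords,
    split_multi_symbol_nodes,
    to_gene_graph,
)


def _record(name, node_specs):
    g = SignedDigraph()
    for spec in node_specs:
        g.add_node(spec)
    return PathwayRecord(name.replace(" ", "_"), name, "db", g)


class TestKeywordSelection:
    def test_matches_pathway_name_case_insensitively(self):
        records = [_record("Wnt signaling", []), _record("MAPK", [])]
        selected = select_pathways_by_keywords(records, ["wnt"])
        assert [r.name for r in selected] == ["Wnt signaling"]

    def test_symbol_only_members_carry_no_catenin_substring(self):
        # CTNNB1 as a symbol does not contain "catenin"; only annotations do
        rec_sym = _record("Glycolysis", [EntityNode("n1", gene_symbols=["CTNNB1"])])
        rec_name = _record(
            "Other", [EntityNode("n2", gene_symbols=[], display_name="beta-catenin")]
        )
        selected = select_pathways_by_keywords([rec_sym, rec_name], ["catenin"])
        assert [r.name for r in selected] == ["Other"]

    def test_keyword_case_folds_against_name(self):
        rec = _record("planar cell polarity (pcp) pathway", [])
        assert select_pathways_by_keywords([rec], ["PCP"]) == [rec]

    def test_empty_keyword_rejected(self):
        with pytest.raises(ValueError):
            select_pathways_by_keywords([_record("x", [])], [""])


class TestMapIdentifiers:
    def test_single_lookup(self, tiny_id_map):
        g = SignedDigraph()
        g.add_node(EntityNode("n1", reference_ids=[("uniprot", "P35222")]))
        mapped = map_identifiers(g, tiny_id_map)
        assert mapped.entity("n1").gene_symbols == ["CTNNB1"]

    def test_duplicate_references_deduplicate(self):
        g = SignedDigraph()
        g.add_node(
            EntityNode("n1", reference_ids=[("entrez", "1"), ("uniprot", "Q1")])
        )
        mapped = map_identifiers(g, {("entrez", "1"): "DVL1", ("uniprot", "Q1"): "DVL1"})
        assert mapped.entity("n1").gene_symbols == ["DVL1"]

    def test_unmappable_node_keeps_display_name_label(self):
        g = SignedDigraph()
        g.add_node(EntityNode("n1", display_name="beta-catenin destruction complex"))
        mapped = map_identifiers(g, {})
        ent = mapped.entity("n1")
        assert ent.gene_symbols == []
        assert ent.label == "beta-catenin destruction complex"


def _classed_graph(edges, classes):
    g = SignedDigraph()
    ids = {u for e in edges for u in e[:2]}
    for nid in sorted(ids):
        g.add_node(
            EntityNode(
                nid,
                entity_class=classes.get(nid, "protein"),
                gene_symbols=[] if nid in classes else [nid],
                display_name="" if nid in classes else nid.lower(),
            )
        )
    for u, v, s in edges:
        g.add_edge(u, v, s)
    return g


class TestFilterNonmappable:
    def test_pass_through_chain(self):
        g = _classed_graph([("A", "X", 1), ("X", "B", 1)], {"X": "small_molecule"})
        out = filter_nonmappable_nodes(g)
        assert out.edges() == {("A", "B", 1)}
        assert "X" not in out

    @pytest.mark.parametrize(
        "s1,s2", [(1, 1), (1, -1), (-1, 1), (-1, -1)], ids=["++", "+-", "-+", "--"]
    )
    def test_rewired_sign_is_product_of_path_signs(self, s1, s2):
        g = _classed_graph([("A", "X", s1), ("X", "B", s2)], {"X": "rna"})
        out = filter_nonmappable_nodes(g)
        assert out.edges() == {("A", "B", s1 * s2)}

    def test_no_removable_nodes_is_identity(self):
        g = _classed_graph([("A", "B", 1), ("B", "C", -1)], {})
        assert filter_nonmappable_nodes(g) == g

    def test_chains_of_removables_traversed_to_fixpoint(self):
        g = _classed_graph(
            [("A", "X", -1), ("X", "Y", -1), ("Y", "B", 1)],
            {"X": "dna", "Y": "nested_pathway"},
        )
        assert filter_nonmappable_nodes(g).edges() == {("A", "B", 1)}

    def test_self_loops_from_rewiring_dropped(self):
        g = _classed_graph([("A", "X", 1), ("X", "A", 1)], {"X": "small_molecule"})
        out = filter_nonmappable_nodes(g)
        assert out.edges() == set()
        assert "A" in out

    def test_node_without_symbol_or_name_removed_with_rewiring(self):
        g = SignedDigraph()
        g.add_node(EntityNode("A", gene_symbols=["A"]))
        g.add_node(EntityNode("blank"))  # no symbols, no display name
        g.add_node(EntityNode("B", gene_symbols=["B"]))
        g.add_edge("A", "blank", -1)
        g.add_edge("blank", "B", -1)
        assert filter_nonmappable_nodes(g).edges() == {("A", "B", 1)}

    @pytest.mark.parametrize("seed", range(8))
    def test_rewiring_matches_signed_closure_oracle(self, seed):
        """On random graphs, filtered edges equal signed reachability through
        the removable subgraph (order-independence + fixpoint soundness)."""
        rng = np.random.default_rng(1000 + seed)
        g = random_signed_digraph(rng, n_nodes=int(rng.integers(6, 13)), p_edge=0.25)
        removable = {n for n in g.node_ids if rng.random() < 0.4}
        for nid in g.node_ids:
            ent = g.entity(nid)
            if nid in removable:
                g.set_entity(
                    EntityNode(nid, entity_class="small_molecule", display_name="x")
                )
            else:
                g.set_entity(
                    EntityNode(nid, entity_class="protein", gene_symbols=[nid])
                )
        expected = signed_reachability(g, removable)
        assert filter_nonmappable_nodes(g).edges() == expected


class TestSplitMerge:
    def test_split_duplicates_incident_edges(self):
        g = SignedDigraph()
        g.add_node(EntityNode("A", gene_symbols=["A"]))
        g.add_node(EntityNode("m", gene_symbols=["G1", "G2"]))
        g.add_edge("A", "m", 1)
        out = split_multi_symbol_nodes(g)
        labels = {out.entity(n).label for n in out.node_ids}
        assert labels == {"A", "G1", "G2"}
        assert {(out.entity(u).label, out.entity(v).label, s) for u, v, s in out.edges()} == {
            ("A", "G1", 1),
            ("A", "G2", 1),
        }

    def test_split_edge_count_is_k_times_incident_set(self):
        g = SignedDigraph()
        for nid in ("A", "B", "C"):
            g.add_node(EntityNode(nid, gene_symbols=[nid]))
        g.add_node(EntityNode("m", gene_symbols=["G1", "G2", "G3"]))
        g.add_edge("A", "m", 1)
        g.add_edge("B", "m", -1)
        g.add_edge("m", "C", 1)
        out = split_multi_symbol_nodes(g)
        # 3 copies x (2 in + 1 out) incident edges
        assert out.n_edges == 9
        assert out.n_nodes == 6

    def test_single_symbol_nodes_unchanged(self):
        g = SignedDigraph.from_edges([("A", "B", 1)])
        assert split_multi_symbol_nodes(g) == g

    def test_merge_unions_edges_under_one_symbol(self):
        g = SignedDigraph()
        g.add_node(EntityNode("n1", gene_symbols=["CTNNB1"]))
        g.add_node(EntityNode("n2", gene_symbols=["CTNNB1"]))
        g.add_node(EntityNode("A", gene_symbols=["A"]))
        g.add_node(EntityNode("B", gene_symbols=["B"]))
        g.add_edge("A", "n1", 1)
        g.add_edge("n2", "B", -1)
        out = merge_same_symbol_nodes(g)
        assert out.edges() == {("A", "CTNNB1", 1), ("CTNNB1", "B", -1)}

    def test_merge_drops_self_loop_between_same_symbol_nodes(self):
        g = SignedDigraph()
        g.add_node(EntityNode("n1", gene_symbols=["GSK3B"]))
        g.add_node(EntityNode("n2", gene_symbols=["GSK3B"]))
        g.add_edge("n1", "n2", 1)
        out = merge_same_symbol_nodes(g)
        assert out.n_nodes == 1 and out.edges() == set()

    def test_merge_collapses_duplicate_parallel_edges(self):
        g = SignedDigraph()
        for nid, sym in (("n1", "X"), ("n2", "X"), ("A", "A")):
            g.add_node(EntityNode(nid, gene_symbols=[sym]))
        g.add_edge("A", "n1", 1)
        g.add_edge("A", "n2", 1)
        assert merge_same_symbol_nodes(g).edges() == {("A", "X", 1)}

    def test_merge_requires_split_first(self):
        g = SignedDigraph()
        g.add_node(EntityNode("m", gene_symbols=["G1", "G2"]))
        with pytest.raises(ValueError, match="split"):
            merge_same_symbol_nodes(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_split_then_merge_edge_count_matches_brute_force(self, seed):
        """With pairwise-distinct symbols per multi-symbol node, split+merge
        edge multiplicity is fully forced; compare against direct expansion."""
        rng = np.random.default_rng(2000 + seed)
        n = int(rng.integers(4, 9))
        g = SignedDigraph()
        symbol_pool = [f"S{i}" for i in range(2 * n)]
        rng.shuffle(symbol_pool)
        node_syms = {}
        for i in range(n):
            nid = f"n{i}"
            k = 2 if rng.random() < 0.4 else 1
            syms = [symbol_pool.pop() for _ in range(k)]
            node_syms[nid] = syms
            g.add_node(EntityNode(nid, gene_symbols=syms))
        for u in node_syms:
            for v in node_syms:
                if u != v and rng.random() < 0.3:
                    g.add_edge(u, v, -1 if rng.random() < 0.3 else 1)
        expected = set()
        for u, v, s in g.edges():
            for su in node_syms[u]:
                for sv in node_syms[v]:
                    if su != sv:
                        expected.add((su, sv, s))
        out = merge_same_symbol_nodes(split_multi_symbol_nodes(g))
        assert out.edges() == expected


def test_full_gene_reduction_pipeline(tiny_pathway, tiny_id_map):
    out = to_gene_graph(tiny_pathway.graph, tiny_id_map)
    assert set(out.node_ids) == {"CTNNB1", "DVL1", "DVL2", "GSK3B"}
    assert out.edges() == {
        ("CTNNB1", "DVL1", -1),
        ("CTNNB1", "DVL2", -1),
        ("DVL1", "GSK3B", 1),
        ("DVL2", "GSK3B", 1),
    }
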