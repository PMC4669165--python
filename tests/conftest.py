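import numpy as np
import pytest
from dataclasses import replace

from wntnet.assembly import assign_groups, build_networks
from wntnet.model import EntityNode, PathwayRecord, SignedDigraph
from wntnet.simulate import (
    plant_connected_terminals,
    round_robin_assignment,
    simulate_expression,
    simulate_pathway_collection,
    synthetic_id_map,
)
from wntnet.transform import to_gene_graph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_pathway():
    """A small mixed pathway: genes, one metabolite, one two-symbol node."""
    graph = SignedDigraph()
    graph.add_node(
        EntityNode("n1", "protein", [("uniprot", "P35222")], [], "beta-catenin")
    )
    graph.add_node(EntityNode("n2", "small_molecule", [], [], "calcium"))
    graph.add_node(
        EntityNode("n3", "protein", [("entrez", "1"), ("entrez", "2")], [], "dvl family")
    )
    graph.add_node(EntityNode("n4", "protein", [("entrez", "3")], [], "gsk3b protein"))
    graph.add_edge("n1", "n2", 1)
    graph.add_edge("n2", "n3", -1)
    graph.add_edge("n3", "n4", 1)
    return PathwayRecord("p1", "wnt canonical toy", "toydb", graph)


@pytest.fixture
def tiny_id_map():
    return {
        ("uniprot", "P35222"): "CTNNB1",
        ("entrez", "1"): "DVL1",
        ("entrez", "2"): "DVL2",
        ("entrez", "3"): "GSK3B",
    }


@pytest.fixture(scope="session")
def sim_study():
    """A full synthetic study: gene-level networks + planted expression data.

    Conditions: 16 overlapping pathways over a 300-gene universe, 20% of
    edges routed through non-gene intermediates, 10% multi-symbol nodes,
    differential expression planted in one connected region of the
    non-canonical network (4-fold shift, sigma 0.5, 5 samples per group).
    """
    records = simulate_pathway_collection(16, 300, p_nongene=0.2, p_multisymbol=0.1, seed=11)
    id_map = synthetic_id_map(300)
    gene_records = [replace(r, graph=to_gene_graph(r.graph, id_map)) for r in records]
    networks = build_networks(assign_groups(gene_records, round_robin_assignment(records)))
    target = networks["noncanonical"]
    planted = plant_connected_terminals(target, 12, seed=12)
    expr, de = simulate_expression(
        target, planted, effect=2.0, sigma=0.5, n_per_group=5, seed=13
    )
    return {
        "records": records,
        "id_map": id_map,
        "networks": networks,
        "planted": planted,
        "expr": expr,
        "de": de,
    }
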