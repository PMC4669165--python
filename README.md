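# wntnet

Signed, directed signaling networks from curated pathway collections,
integrated with differential-expression data.

`wntnet` is built for the analysis style used to model WNT signaling in
breast cancer: pathway knowledge exported from databases (BioCarta,
Reactome, KEGG, PID, Pathway Commons) is reduced to gene-level graphs whose
directed edges carry a sign — `+1` for activation, `-1` for inhibition —
stratified by expert curation into four conceptual groups (canonical
β-catenin-dependent signaling, non-canonical signaling, inhibition of
canonical signaling, regulation of signaling) and merged into one network
per group. Differential-expression results are then laid over these
networks three ways:

* **gene-set enrichment** — over-representation of significant DEGs in
  network gene sets by a one-sided Fisher's exact test
  (hypergeometric tail over the measured universe), and a ranking-based
  one-sided Wilcoxon rank-sum test for long DEG lists;
* **module extraction** — DEG-matched nodes become terminals of an
  approximate Steiner tree (Kou–Markowsky–Berman heuristic on the
  undirected hop metric); the *module* is the network's induced signed
  subgraph on the tree nodes, with non-DEG *Steiner nodes* introduced only
  to maintain connectivity;
* **cross-platform validation** — node/edge overlap of a module pair
  relative to a reference module, Pearson correlation of log fold-changes
  over shared genes (Fisher-z confidence interval), and the fate of each
  reference Steiner node in the validation module.

Network descriptive tools (degree and betweenness centralities, top-k
"key node" overlap, greedy-modularity communities) and a first-class
synthetic-data generator (pathway collections with non-gene entities and
multi-symbol nodes; two-group expression with planted DE genes) round out
the pipeline, so every stage runs and is tested without any download.

## Worked example

```python
from dataclasses import replace
from wntnet import (
    assign_groups, build_networks, extract_module, fisher_overrepresentation,
    select_degs, to_gene_graph, GeneSet,
)
from wntnet.simulate import (
    plant_connected_terminals, round_robin_assignment,
    simulate_expression, simulate_pathway_collection, synthetic_id_map,
)

records = simulate_pathway_collection(n_pathways=12, genes=200, seed=1)
id_map = synthetic_id_map(200)
gene_records = [replace(r, graph=to_gene_graph(r.graph, id_map)) for r in records]
networks = build_networks(assign_groups(gene_records, round_robin_assignment(records)))
net = networks["noncanonical"]
print({g: (n.n_nodes, n.n_edges) for g, n in networks.items()})

planted = plant_connected_terminals(net, 10, seed=3)
_, de = simulate_expression(net, planted, effect=3, sigma=0.5, n_per_group=5, seed=4)
up, down = select_degs(de, alpha=0.05)
module = extract_module(net, up, down, de)
universe = GeneSet("universe", frozenset(de["gene"]))
p = fisher_overrepresentation(up | down, GeneSet("planted", planted.genes), universe)
print(len(up), len(down), module.graph.n_nodes, len(module.terminals),
      len(module.steiner_nodes), f"{p:.3g}")
```

prints

```
{'canonical': (70, 208), 'noncanonical': (60, 166), 'inhibition': (77, 212), 'regulation': (71, 200)}
10 0 12 10 2 3.06e-18
```

i.e. the four merged networks have 60–77 genes each; all ten planted genes
are recovered as up-regulated DEGs; the extracted module has 12 nodes —
the ten terminals plus two Steiner nodes introduced to keep them connected;
and the planted gene set is massively over-represented among the DEGs
(Fisher p ≈ 3e-18).

The same stages are available as a CLI:

```
wntnet simulate -o out_dir=run -o seed=5
wntnet build    -o edge_file=run/pathways.edges.tsv -o node_file=run/pathways.nodes.tsv \
                -o id_map=run/id_map.tsv -o assignment=run/groups.tsv -o out_dir=run/nets
wntnet analyze  -o network=run/nets/noncanonical.sif -o out_dir=run/analysis
wntnet enrich   -o de_table=run/de_table.tsv -o canonical=run/nets/canonical.sif \
                -o noncanonical=run/nets/noncanonical.sif -o out_dir=run/enrich
wntnet modules  -o network=run/nets/noncanonical.sif -o de_table=run/de_table.tsv -o out_dir=run/mods
wntnet validate -o ref_edges=... -o ref_nodes=... -o val_edges=... -o val_nodes=... \
                -o ref_de=... -o val_de=... -o out_dir=run/validate
```

Every subcommand also accepts a flat YAML config (`-c config.yaml`) and
writes a JSON run manifest next to its outputs.

## Layout

```
src/wntnet/
  model.py       signed digraph, entity annotations, pathway records
  io.py          pathway-exchange, SIF, DE-table, GMT readers/writers
  transform.py   id mapping, connectivity-preserving filtering, split/merge
  assembly.py    group assignment, component splitting, network merging
  analytics.py   centralities, key nodes, communities, gene subnetworks
  enrichment.py  probe summarisation, Bonferroni, DEG selection, Fisher/Wilcoxon
  steiner.py     terminal mapping, KMB Steiner tree, module induction/export
  validation.py  graph overlap, fold-change correlation, Steiner concordance
  simulate.py    synthetic pathway collections and expression data
  reference.py   loaders for the published supplementary tables
  cli.py         subcommand orchestration
```

See `docs/methods.md` for the modeling choices and their rationale.
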