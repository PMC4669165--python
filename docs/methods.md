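# Methods

## Graph model

The carrier structure is a directed multigraph whose nodes are annotated
molecular entities and whose edges carry a sign: `+1` activation, `-1`
inhibition. An edge is identified by the full `(source, target, sign)`
triple, so a pair of genes may be connected by two antiparallel-signed
edges (databases do report both an activating and an inhibiting influence
between the same ordered pair, typically context-dependent); deduplication
during merging removes only identical triples. Self-loops are rejected at
construction and silently dropped whenever a transformation (rewiring,
node merging) would create one — the downstream algorithms (Steiner trees,
modularity) assume loop-free graphs and a gene's self-influence carries no
information for expression overlay.

Binding/complex-formation and conversion semantics are out of scope: the
pathway exchange format represents already-flattened *controlling*
interactions, as produced by interaction-graph transforms of BioPAX level 3
exports. Parsing the original OWL/RDF is deliberately not reimplemented;
the tabular exchange format (edge table + entity annotation table) is the
package's input boundary.

## Gene-graph reduction

1. **Identifier mapping.** Each entity's database references (Entrez,
   UniProt, …) are mapped to HGNC symbols; symbols are deduplicated with
   stable order. Entities with no mappable reference keep their free-text
   instance name as the node label — dropping them outright would
   discard curated hub entities such as named complexes.
2. **Non-gene filtering with rewiring.** Small molecules, DNA, RNA and
   nested-pathway nodes cannot be matched to expression data and are
   removed, as are nodes with neither a symbol nor a display name. For
   every removed node, each (in-neighbour, out-neighbour) pair is
   reconnected; the new edge's sign is the *product* of the signs along the
   bypassed path (inhibition of an inhibitor activates — the standard
   convention for signed path effects). The implementation computes
   sign-annotated reachability through the entire removable subgraph
   (states are node × sign-parity pairs), so chains of removable nodes are
   traversed to fixpoint and the result is provably independent of any
   removal order; this is verified against a boolean matrix-closure oracle
   in the tests. A walk through a negative cycle inside the removable
   region can legitimately yield both signs for the same gene pair; both
   edges are kept.
3. **Split and merge.** A node annotated with k > 1 symbols becomes k
   single-symbol nodes, each inheriting all incident edges with directions
   and signs. Conversely, all nodes sharing a label are merged (edges
   relabeled and unioned); node identifiers are canonicalised to the label
   itself — the single symbol for gene nodes, the display name otherwise —
   so that SIF round-trips are label-stable. Merging by display name for
   unmapped entities extends the published same-symbol rule by analogy;
   distinct unmapped entities keep distinct names and are unaffected.

## Assembly

Group membership (canonical / non-canonical / inhibition / regulation /
discarded) is expert curation and therefore an explicit input file, never
re-derived; keyword selection (`wnt`, `catenin`, `pcp`, …) exists as a
screening aid but does not reproduce curation. Mixed pathways can be split
by weakly connected component, with a representative node naming each
component's group ("connected" is read direction-blind, the natural choice
for membership questions). Merging a group unions the members'
interaction triples (set semantics: idempotent, commutative, associative)
and keeps only nodes incident to an edge.

## Analytics

* **Degree** counts all incident signed edges (parallel edges included).
* **Betweenness** is computed on the directed unweighted simple projection
  with fractional credit among tied shortest paths (Brandes, as in
  networkx). Treating the graph as directed follows the default of the
  igraph implementations this analysis style relies on; signs are ignored —
  a path's regulatory effect does not alter its topological load.
* **Key nodes** are the intersection of the top-k-by-degree and
  top-k-by-betweenness lists (default k = 15). Ties at rank k are all
  included, so a list may exceed k; this is the only deterministic reading
  of "the k highest scored nodes" under ties.
* **Communities** come from greedy (Clauset–Newman–Moore) modularity
  maximisation on the undirected, unweighted, loop-free projection —
  the agglomerative merge path is cut at maximal modularity. The networkx
  implementation is used; it is deterministic for a given graph, and its
  results are cross-checked in the tests against exhaustive partition
  enumeration (8-node graphs) and against igraph's fastgreedy.

## Enrichment

* Probe-level tables are summarised by keeping, per gene, the probe with
  the smallest p-value (ties: larger |log fold-change|, then lexicographic
  probe id). Bonferroni adjustment is `min(1, p·m)`.
* DEGs are `adj_p < α` (default α = 0.05) split by fold-change sign; a
  significant gene with log-FC exactly 0 has no direction and is excluded
  with a warning.
* **Fisher over-representation** is the one-sided hypergeometric upper
  tail of the observed DEG/gene-set overlap. The universe is *all measured
  genes* (all rows of the summarised DE table): enrichment claims are
  relative to what the platform could have detected. The gene set is
  intersected with the universe first.
* **Wilcoxon rank-sum enrichment** ranks the full table by p-value
  ascending and tests, one-sided, whether in-set genes rank higher
  (i.e. have smaller p-values) than the rest. Exact enumeration is used
  for universes ≤ 50 without ties, otherwise the normal approximation with
  tie correction. Both the ranking column and the test's one-sidedness are
  arguments, since other rankings (|log FC|) are defensible.

## Steiner modules

DEG symbols are matched to network node labels; matched nodes are
restricted to the largest connected component of the undirected projection
(the tree heuristic needs a connected host) and the discarded symbols are
reported, never silently lost. The Steiner tree is approximated with the
Kou–Markowsky–Berman heuristic on the undirected hop metric: metric
closure over terminals → minimum spanning tree → shortest-path expansion →
spanning tree of the expansion → pruning of non-terminal leaves. This
matches the minimum-spanning-tree framing of the SteinerNet-style analysis;
edge weights are uniform because the networks carry none. All ties
(BFS shortest paths, both MST stages) break lexicographically, making the
tree a pure function of the graph and terminal set; the tests verify tree
validity and the ≤ 2× optimality guarantee against exhaustive search.
Because the heuristic (and any heuristic) selects one of possibly many
near-optimal trees, *terminal* counts are heuristic-independent but exact
Steiner-node identities are best-effort.

The **module** is the source network's induced signed subgraph on the tree
nodes — all directed signed edges between them, not just tree edges —
with terminals carrying their log fold-change. For export, display values
are clamped to ±cap (defaults 3 for microarray-scale, 4 for RNA-Seq-scale
fold-changes, where colour scales saturate); raw values are preserved in a
separate column.

## Validation

The earlier-platform module is the reference. Node overlap is
|V_ref ∩ V_val| / |V_ref|; edge overlap uses ordered node pairs with signs
ignored by default (`respect_sign=True` is available), since a sign
disagreement between platforms still confirms the interaction's presence.
Fold-change concordance is the Pearson correlation over genes present in
both modules and carrying log fold-changes in both DE tables (DE tables of
this analysis style list only significant genes, so this restricts to
genes significant on both platforms); the 95% CI uses the Fisher
z-transform. Each reference Steiner node is classified in the validation
module as confirmed-as-Steiner, confirmed-as-DEG (present as a terminal),
or unconfirmed; the three counts partition the reference Steiner set.

## Synthetic data

The generator emulates what the real inputs look like structurally, not
biologically:

* **Collections** draw each pathway's members from a shared universe
  (membership overlap between pathways is what makes merging non-trivial),
  wire them with a random spanning tree plus extra arcs (connected, ~2.5
  edges/node — the sparse-but-cyclic regime of curated pathway graphs),
  sign edges 3:1 activation:inhibition (activation dominates database
  annotations), route each edge through a non-gene intermediate with
  probability `p_nongene` (default 0.2) and give each gene node a second
  symbol with probability `p_multisymbol` (default 0.1). Nodes carry
  reference ids but no symbols, so identifier mapping is exercised.
* **Expression** is independent Gaussian log2 intensity: per-gene baseline
  N(7, 1), planted genes shifted by `effect` in group B, noise sigma
  (default 0.5, a typical residual SD for array data), defaults of 3–5
  samples per group as in small cell-line designs. DE tables come from
  per-gene two-sample t-tests with Bonferroni adjustment — a deliberately
  plain stand-in for limma/edgeR moderated fits, acceptable because the
  pipeline consumes DE tables agnostically. Power at the study conditions
  (effect 3 log2 units, sigma 0.5, n = 5) is ≥ 95% per planted gene under
  Bonferroni; at effect 2 it falls to roughly 40%, which the type-I/power
  tests document.
* **Planted terminals** are sampled from a BFS neighbourhood of about three
  times the requested size inside the largest component, so they are
  mutually reachable but not adjacent — leaving room for genuine Steiner
  nodes.

What passing tests on this generator do *not* show: correlated noise,
mean–variance coupling, probe effects, count overdispersion, or biological
pathway topology (hubs, motifs); conclusions about real platforms rest on
the statistical procedures, which are validated against closed-form and
enumeration oracles independently of the generator.

The acceptance script runs this study at 24 pathways / 400-gene universe /
20 planted terminals with an effect of 3 log2 units — sizes chosen to be
curation-scale (the published collection had 26 pathways) while keeping
every stage comfortably in the seconds range.

## Numerical and degenerate-input choices

* Fisher uses the survival function of the hypergeometric distribution
  (`P(X ≥ k)` via `sf(k-1)`), exact, no normal approximation.
* Pearson p-values use the t transform (scipy); CIs the Fisher z.
* Rank-k centrality cutoffs include ties; graphs smaller than k use all
  nodes (logged).
* Empty graphs: centralities, community detection and gene-set
  construction raise; filtering that removes every node returns an empty
  graph with a warning (an empty result is meaningful there).
* Fewer than 3 genes shared between modules: fold-change correlation
  raises (module report records NaN); fewer than 3 shared DEGs across
  platforms: count reported, correlation omitted with a warning.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical outputs.

## Known limitations

* The exchange format cannot represent isolated nodes in SIF output (by
  design: merged networks exclude interaction-free nodes).
* Signed-edge semantics stop at sign products; no kinetic, dosage or
  context information is modeled.
* The Wilcoxon exact path is limited to small universes without ties;
  large-universe p-values are asymptotic.
* Reference analyses of the published supplementary tables require the
  user to supply those tables as plain text (`wntnet.reference`); they are
  not redistributed.
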