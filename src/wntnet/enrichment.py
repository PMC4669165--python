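"""Differential-expression utilities and gene-set enrichment tests.

Two complementary tests are provided.  Over-representation asks whether a
gene set contains more significant DEGs than expected under hypergeometric
sampling from the measured universe (one-sided Fisher's exact test).  The
ranking-based alternative asks whether genes of a set rank systematically
better (smaller p-values) than the remaining genes, via a one-sided Wilcoxon
rank-sum test — preferable when the DEG list is very long and nearly any set
overlaps it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import SignedDigraph

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "summarize_probes",
    "bonferroni",
    "select_degs",
    "build_gene_sets",
    "fisher_overrepresentation",
    "wilcoxon_set_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of HGNC gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genes", frozenset(g.strip().upper() for g in self.genes if g.strip())
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __or__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.name}|{other.name}", self.genes | other.genes)


def summarize_probes(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-level DE table to one row per gene.

    For each gene the probe with the smallest p-value is kept; ties are
    broken by larger absolute log fold-change, then by lexicographic
    probe id.  Rows must carry ``probe_id`` and ``gene``.
    """
    if "probe_id" not in table.columns:
        raise ValueError("probe-level table requires a probe_id column")
    df = table.copy()
    df["_abs_lfc"] = -df["log_fc"].abs()
    df = df.sort_values(
        ["gene", "p_value", "_abs_lfc", "probe_id"], kind="stable"
    ).drop_duplicates("gene", keep="first")
    return df.drop(columns="_abs_lfc").reset_index(drop=True)


def bonferroni(p_values) -> np.ndarray:
    """Family-wise error correction: ``min(1, p * m)`` with m the family size."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def select_degs(table: pd.DataFrame, alpha: float = 0.05) -> tuple[GeneSet, GeneSet]:
    """Split significant genes into up- and down-regulated sets.

    ``up`` holds genes with ``adj_p < alpha`` and positive log fold-change,
    ``down`` those with negative log fold-change.  Significant genes with a
    log fold-change of exactly zero belong to neither direction and are
    excluded with a warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if table["gene"].duplicated().any():
        raise ValueError("table must be summarized to one row per gene")
    sig = table[table["adj_p"] < alpha]
    zero = sig[sig["log_fc"] == 0]
    if len(zero):
        logger.warning(
            "%d significant gene(s) with log_fc == 0 excluded from both DEG lists", len(zero)
        )
    up = GeneSet("up", frozenset(sig.loc[sig["log_fc"] > 0, "gene"]))
    down = GeneSet("down", frozenset(sig.loc[sig["log_fc"] < 0, "gene"]))
    return up, down


def build_gene_sets(canonical: SignedDigraph, noncanonical: SignedDigraph) -> list[GeneSet]:
    """The six gene sets derived from the canonical/non-canonical networks.

    Returns, in order: the two full node-label sets, both relative
    complements, the intersection, and the union.
    """
    if canonical.n_nodes == 0 or noncanonical.n_nodes == 0:
        raise ValueError("both networks must be non-empty")
    can = frozenset(canonical.entity(n).label for n in canonical.node_ids)
    noncan = frozenset(noncanonical.entity(n).label for n in noncanonical.node_ids)
    return [
        GeneSet("canonical", can),
        GeneSet("noncanonical", noncan),
        GeneSet("can\\noncan", can - noncan),
        GeneSet("noncan\\can", noncan - can),
        GeneSet("can∩noncan", can & noncan),
        GeneSet("can∪noncan", can | noncan),
    ]


def fisher_overrepresentation(degs: GeneSet, gene_set: GeneSet, universe: GeneSet) -> float:
    """One-sided Fisher's exact test for over-representation.

    Tests whether the overlap between the DEG list and the gene set exceeds
    the hypergeometric expectation over the measured universe.  The gene set
    is intersected with the universe before testing; the DEG list must be a
    subset of the universe.
    """
    uni = universe.genes
    if not uni:
        raise ValueError("universe is empty")
    if not degs.genes <= uni:
        raise ValueError("DEG list is not a subset of the universe")
    in_set = gene_set.genes & uni
    if not in_set:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the universe")
    n_universe = len(uni)
    n_set = len(in_set)
    n_degs = len(degs.genes)
    overlap = len(degs.genes & in_set)
    # upper tail P(X >= overlap), X ~ Hypergeom(N, K, n)
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_set, n_degs))


def wilcoxon_set_enrichment(
    table: pd.DataFrame, gene_set: GeneSet, rank_by: str = "p_value"
) -> float:
    """One-sided Wilcoxon rank-sum enrichment of a gene set in a ranking.

    The DE table must cover the full tested universe (all measured genes,
    not only significant ones).  Genes are ranked by ``rank_by`` ascending
    (default: p-value, so rank 1 is the most significant gene) and the
    in-set genes are compared against all others under the alternative that
    in-set genes rank higher, i.e. have smaller values.  Exact enumeration
    is used for universes of at most 50 genes without ties; otherwise the
    normal approximation with tie correction.
    """
    if rank_by not in table.columns:
        raise ValueError(f"rank_by column {rank_by!r} not in table")
    values = table[rank_by].to_numpy(dtype=float)
    in_set = table["gene"].isin(gene_set.genes).to_numpy()
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == len(table):
        raise ValueError(
            f"gene set {gene_set.name!r} must cover a proper non-empty subset of the table"
        )
    x, y = values[in_set], values[~in_set]
    exact = len(values) <= 50 and len(np.unique(values)) == len(values)
    res = stats.mannwhitneyu(
        x, y, alternative="less", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)
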