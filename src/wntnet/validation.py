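"""Cross-dataset concordance of differentially regulated modules.

A module derived from one expression platform (the *reference*, e.g.
microarray) is compared against its counterpart from an independent platform
(the *validation* module, e.g. RNA-Seq) in four ways: node/edge graph
overlap relative to the reference, Pearson correlation of log fold-changes
over shared genes, the fate of the reference's Steiner nodes in the
validation module, and the overlap of the two platforms' significant gene
lists.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet
from .model import SignedDigraph
from .steiner import SteinerModule

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapReport",
    "graph_overlap",
    "foldchange_correlation",
    "steiner_concordance",
    "deg_overlap",
    "build_overlap_report",
]


@dataclass
class SteinerConcordance:
    """Fate of the reference module's Steiner nodes in the validation module."""

    confirmed_as_steiner: int
    confirmed_as_deg: int
    unconfirmed: int

    @property
    def total(self) -> int:
        return self.confirmed_as_steiner + self.confirmed_as_deg + self.unconfirmed


@dataclass
class OverlapReport:
    """All concordance measures of one module pair."""

    node_overlap: float
    edge_overlap: float
    n_ref_nodes: int
    n_ref_edges: int
    fc_correlation: float
    fc_p_value: float
    fc_ci_low: float
    fc_ci_high: float
    steiner: SteinerConcordance

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        flat = asdict(self)
        flat.update(flat.pop("steiner"))
        return pd.DataFrame([flat])


def graph_overlap(
    reference: SignedDigraph, other: SignedDigraph, respect_sign: bool = False
) -> tuple[float, float]:
    """Fractions of the reference's nodes and edges present in ``other``.

    Edge identity defaults to the ordered ``(source, target)`` pair with
    signs ignored; set ``respect_sign`` to compare full signed triples.
    """
    if reference.n_nodes == 0:
        raise ValueError("reference graph is empty")
    ref_nodes, other_nodes = set(reference.node_ids), set(other.node_ids)
    node_overlap = len(ref_nodes & other_nodes) / len(ref_nodes)

    def edge_ids(g: SignedDigraph) -> set:
        if respect_sign:
            return g.edges()
        return {(u, v) for u, v, _ in g.edges()}

    ref_edges = edge_ids(reference)
    edge_overlap = len(ref_edges & edge_ids(other)) / len(ref_edges) if ref_edges else 0.0
    return node_overlap, edge_overlap


def foldchange_correlation(
    ref_module: SteinerModule,
    val_module: SteinerModule,
    ref_de: pd.DataFrame,
    val_de: pd.DataFrame,
) -> tuple[float, float, tuple[float, float]]:
    """Pearson correlation of log fold-changes over the modules' shared genes.

    Considers genes present in both modules' node sets that carry a log
    fold-change in both DE tables.  Returns ``(r, two-sided p, 95% CI)``;
    the confidence interval comes from the Fisher z-transform.
    """
    shared = set(ref_module.graph.node_ids) & set(val_module.graph.node_ids)
    ref_fc = dict(zip(ref_de["gene"], ref_de["log_fc"]))
    val_fc = dict(zip(val_de["gene"], val_de["log_fc"]))
    genes = sorted(g for g in shared if g in ref_fc and g in val_fc)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} overlap gene(s) carry fold-changes in both tables")
    x = np.array([ref_fc[g] for g in genes])
    y = np.array([val_fc[g] for g in genes])
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=0.95)
    return float(res.statistic), float(res.pvalue), (float(ci.low), float(ci.high))


def steiner_concordance(
    ref_module: SteinerModule, val_module: SteinerModule, val_degs: GeneSet
) -> SteinerConcordance:
    """Classify each reference Steiner node by its status in the validation module.

    ``confirmed_as_steiner``: present with role steiner; ``confirmed_as_deg``:
    present as a terminal (a significant DEG on the validation platform);
    ``unconfirmed``: absent from the validation module.  The three counts
    partition the reference Steiner set.
    """
    as_steiner = as_deg = unconfirmed = 0
    val_roles = val_module.node_roles
    for node in ref_module.steiner_nodes:
        role = val_roles.get(node)
        if role == "steiner":
            as_steiner += 1
        elif role == "terminal" and node in val_degs.genes:
            as_deg += 1
        elif role == "terminal":
            # terminal status implies DEG membership; count it even if the
            # caller passed a narrower DEG set
            as_deg += 1
        else:
            unconfirmed += 1
    return SteinerConcordance(as_steiner, as_deg, unconfirmed)


def deg_overlap(
    de_a: pd.DataFrame, de_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[int, float | None]:
    """Cross-platform DEG overlap and fold-change correlation.

    Returns the number of genes significant (``adj_p < alpha``) in both
    tables and the Pearson correlation of their log fold-changes over that
    overlap (``None``, with a warning, when fewer than 3 genes overlap).
    """
    for name, df in (("first", de_a), ("second", de_b)):
        if df["gene"].duplicated().any():
            raise ValueError(f"{name} table must be summarized to one row per gene")
    sig_a = de_a[de_a["adj_p"] < alpha]
    sig_b = de_b[de_b["adj_p"] < alpha]
    shared = sorted(set(sig_a["gene"]) & set(sig_b["gene"]))
    if len(shared) < 3:
        logger.warning("only %d overlapping DEG(s); correlation omitted", len(shared))
        return len(shared), None
    fc_a = sig_a.set_index("gene").loc[shared, "log_fc"].to_numpy(dtype=float)
    fc_b = sig_b.set_index("gene").loc[shared, "log_fc"].to_numpy(dtype=float)
    r = float(stats.pearsonr(fc_a, fc_b).statistic)
    return len(shared), r


def build_overlap_report(
    ref_module: SteinerModule,
    val_module: SteinerModule,
    ref_de: pd.DataFrame,
    val_de: pd.DataFrame,
    val_degs: GeneSet,
) -> OverlapReport:
    """Assemble the full concordance report for one module pair."""
    node_ov, edge_ov = graph_overlap(ref_module.graph, val_module.graph)
    try:
        r, p, (lo, hi) = foldchange_correlation(ref_module, val_module, ref_de, val_de)
    except ValueError:
        r = p = lo = hi = math.nan
    return OverlapReport(
        node_overlap=node_ov,
        edge_overlap=edge_ov,
        n_ref_nodes=ref_module.graph.n_nodes,
        n_ref_edges=len({(u, v) for u, v, _ in ref_module.graph.edges()}),
        fc_correlation=r,
        fc_p_value=p,
        fc_ci_low=lo,
        fc_ci_high=hi,
        steiner=steiner_concordance(ref_module, val_module, val_degs),
    )
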