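"""Readers and writers for the pipeline's tabular exchange formats.

All formats are UTF-8 TSV with a header row:

* **pathway exchange** — two files emulating parsed pathway-database graphs:
  an edge table (``pathway_id, source, target, sign``) and an entity
  annotation table (``pathway_id, node_id, entity_class, reference_ids,
  gene_symbols, display_name``), reference ids semicolon-joined as
  ``namespace:id`` and symbols semicolon-joined.
* **SIF** — signed edge list ``source, target, weight`` with weight 1
  (activation) or -1 (inhibition).  Isolated nodes are not representable.
* **DE table** — per-gene differential expression:
  ``gene, log_fc, p_value, adj_p`` plus optional ``probe_id``.
* **gene sets** — GMT (name, description, then symbols) or one symbol per
  line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .model import EntityNode, GraphIntegrityError, PathwayRecord, SignedDigraph

__all__ = [
    "PathwayFormatError",
    "read_pathway_exchange",
    "write_pathway_exchange",
    "read_sif",
    "write_sif",
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_id_map",
    "read_group_assignment",
]


class PathwayFormatError(ValueError):
    """A file does not conform to the documented exchange format."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PathwayFormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def _split_field(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    return [part for part in str(value).split(";") if part]


# ---------------------------------------------------------------------------
# pathway exchange format


def read_pathway_exchange(edge_file, node_file) -> list[PathwayRecord]:
    """Read a pathway collection from an edge table and a node annotation table.

    Returns one :class:`PathwayRecord` per distinct ``pathway_id`` (group
    ``unassigned``).  Optional node-table columns ``pathway_name`` and
    ``source_db`` populate the record's provenance.

    Raises
    ------
    PathwayFormatError
        If a required column is absent.
    GraphIntegrityError
        If an edge references a node missing from the annotation table.
    ValueError
        If an edge sign is outside ``{1, -1}``.
    """
    edges = pd.read_csv(edge_file, sep="\t", dtype=str, keep_default_na=False)
    nodes = pd.read_csv(node_file, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(edges, ["pathway_id", "source", "target", "sign"], edge_file)
    _require_columns(
        nodes,
        ["pathway_id", "node_id", "entity_class", "reference_ids", "gene_symbols", "display_name"],
        node_file,
    )

    records: dict[str, PathwayRecord] = {}
    meta: dict[str, tuple[str, str]] = {}
    for row in nodes.itertuples(index=False):
        pid = row.pathway_id
        if pid not in records:
            name = getattr(row, "pathway_name", pid) or pid
            source_db = getattr(row, "source_db", "") or ""
            meta[pid] = (name, source_db)
            records[pid] = PathwayRecord(
                pathway_id=pid, name=name, source_db=source_db, graph=SignedDigraph()
            )
        refs = [tuple(r.split(":", 1)) for r in _split_field(row.reference_ids)]
        refs = [(ns, rid) for ns, rid in (r if len(r) == 2 else (r[0], "") for r in refs)]
        records[pid].graph.add_node(
            EntityNode(
                node_id=row.node_id,
                entity_class=row.entity_class,
                reference_ids=refs,
                gene_symbols=_split_field(row.gene_symbols),
                display_name=row.display_name,
            )
        )

    dangling: list[str] = []
    for row in edges.itertuples(index=False):
        pid = row.pathway_id
        if pid not in records:
            dangling.extend([f"{pid}/{row.source}", f"{pid}/{row.target}"])
            continue
        try:
            sign = int(row.sign)
        except ValueError:
            raise ValueError(f"{edge_file}: non-integer sign {row.sign!r}") from None
        if sign not in (1, -1):
            raise ValueError(f"{edge_file}: sign must be 1 or -1, got {sign}")
        graph = records[pid].graph
        missing = [n for n in (row.source, row.target) if n not in graph]
        if missing:
            dangling.extend(f"{pid}/{n}" for n in missing)
            continue
        graph.add_edge(row.source, row.target, sign)
    if dangling:
        raise GraphIntegrityError(
            "edge file references unannotated node(s): " + ", ".join(sorted(set(dangling)))
        )
    return list(records.values())


def write_pathway_exchange(records: Iterable[PathwayRecord], edge_file, node_file) -> None:
    """Write a pathway collection in the two-file exchange format."""
    edge_rows, node_rows = [], []
    for rec in records:
        for u, v, s in sorted(rec.graph.edges()):
            edge_rows.append((rec.pathway_id, u, v, s))
        for node_id in sorted(rec.graph.node_ids):
            ent = rec.graph.entity(node_id)
            node_rows.append(
                (
                    rec.pathway_id,
                    ent.node_id,
                    ent.entity_class,
                    ";".join(f"{ns}:{rid}" for ns, rid in ent.reference_ids),
                    ";".join(ent.gene_symbols),
                    ent.display_name,
                    rec.name,
                    rec.source_db,
                )
            )
    pd.DataFrame(edge_rows, columns=["pathway_id", "source", "target", "sign"]).to_csv(
        edge_file, sep="\t", index=False
    )
    pd.DataFrame(
        node_rows,
        columns=[
            "pathway_id",
            "node_id",
            "entity_class",
            "reference_ids",
            "gene_symbols",
            "display_name",
            "pathway_name",
            "source_db",
        ],
    ).to_csv(node_file, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simple interaction format


def read_sif(path) -> SignedDigraph:
    """Read a signed edge list; weight must be 1 or -1 on every data row."""
    graph = SignedDigraph()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:3]] != ["source", "target", "weight"]:
            raise PathwayFormatError(
                f"{path}: expected header 'source\\ttarget\\tweight', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise PathwayFormatError(f"{path}: line {lineno}: expected 3 columns")
            u, v, w = row[0], row[1], row[2]
            try:
                sign = int(w)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer weight {w!r}") from None
            if sign not in (1, -1):
                raise ValueError(f"{path}: line {lineno}: weight must be 1 or -1, got {sign}")
            for endpoint in (u, v):
                if endpoint not in graph:
                    graph.add_node(endpoint)
            graph.add_edge(u, v, sign)
    return graph


def write_sif(graph: SignedDigraph, path) -> Path:
    """Write the graph's edges as a SIF file (isolated nodes are dropped)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for u, v, s in sorted(graph.edges()):
            writer.writerow([u, v, s])
    return path


# ---------------------------------------------------------------------------
# DE tables, gene sets, mappings

DE_COLUMNS = ["gene", "log_fc", "p_value", "adj_p"]


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, DE_COLUMNS, path)
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    return df


def write_de_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = DE_COLUMNS + (["probe_id"] if "probe_id" in df.columns else [])
    df.to_csv(path, sep="\t", index=False, columns=cols)
    return path


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT: name, description, then one symbol per column."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {p.strip().upper() for p in parts[2:] if p.strip()}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "") -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(set(genes))]) + "\n")
    return path


def read_gene_list(path) -> list[str]:
    """One symbol per line; blanks ignored; order preserved, duplicates kept."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def read_id_map(path) -> dict[tuple[str, str], str]:
    """TSV columns ``namespace, id, symbol`` -> ``{(namespace, id): SYMBOL}``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["namespace", "id", "symbol"], path)
    return {
        (row.namespace, row.id): row.symbol.strip().upper() for row in df.itertuples(index=False)
    }


def read_group_assignment(path) -> dict[str, str]:
    """TSV columns ``pathway_id, group`` -> assignment mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["pathway_id", "group"], path)
    return {row.pathway_id: row.group for row in df.itertuples(index=False)}
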