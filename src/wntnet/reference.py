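"""Loaders for the published WNT reference tables.

The published supplementary material distributes the four merged WNT
networks (SIF), the 121-gene literature list, the microarray and RNA-Seq
DEG tables, and the original/validation module edge lists as spreadsheet
attachments of the article; they are not redistributed with this package.
To run the reference-data analyses, convert those attachments to the
package's plain-text formats and place them under a directory (default
``data/reference``) as:

* ``s2_canonical.sif``, ``s2_noncanonical.sif``, ``s2_inhibition.sif``,
  ``s2_regulation.sif`` — the four networks (``source  target  weight``);
* ``s3_genes.txt`` — the literature gene list, one HGNC symbol per line;
* ``s4_microarray_degs.tsv``, ``s5_rnaseq_degs.tsv`` — DE tables
  (``gene  log_fc  p_value  adj_p``);
* ``s6_<network>_<which>.edges.tsv`` / ``.nodes.tsv`` with ``network`` in
  ``{canonical, noncanonical}`` and ``which`` in ``{original, validation}``
  — module exports in this package's module format.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import read_de_table, read_gene_list, read_sif
from .model import SignedDigraph
from .steiner import SteinerModule, read_module

__all__ = [
    "DEFAULT_REFERENCE_DIR",
    "load_reference_networks",
    "load_reference_gene_list",
    "load_reference_de_table",
    "load_reference_module",
]

DEFAULT_REFERENCE_DIR = Path("data/reference")

NETWORK_GROUPS = ("canonical", "noncanonical", "inhibition", "regulation")


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"reference table {path} is not present; the published supplementary "
            "spreadsheets must be converted to the documented plain-text formats "
            "and placed there (see wntnet.reference module docstring)"
        )
    return path


def load_reference_networks(directory=DEFAULT_REFERENCE_DIR) -> dict[str, SignedDigraph]:
    """The four published WNT networks keyed by group."""
    directory = Path(directory)
    return {g: read_sif(_require(directory / f"s2_{g}.sif")) for g in NETWORK_GROUPS}


def load_reference_gene_list(directory=DEFAULT_REFERENCE_DIR) -> list[str]:
    """The literature-reviewed WNT gene list (121 symbols)."""
    return read_gene_list(_require(Path(directory) / "s3_genes.txt"))


def load_reference_de_table(platform: str, directory=DEFAULT_REFERENCE_DIR) -> pd.DataFrame:
    """The published DEG table for ``platform`` in {microarray, rnaseq}."""
    names = {"microarray": "s4_microarray_degs.tsv", "rnaseq": "s5_rnaseq_degs.tsv"}
    if platform not in names:
        raise ValueError(f"platform must be one of {sorted(names)}, got {platform!r}")
    return read_de_table(_require(Path(directory) / names[platform]))


def load_reference_module(
    network: str, which: str, directory=DEFAULT_REFERENCE_DIR
) -> SteinerModule:
    """A published module export: ``network`` canonical/noncanonical, ``which`` original/validation."""
    if network not in ("canonical", "noncanonical") or which not in ("original", "validation"):
        raise ValueError(f"unknown module {network!r}/{which!r}")
    stem = Path(directory) / f"s6_{network}_{which}"
    return read_module(
        _require(stem.with_suffix(".edges.tsv")),
        _require(stem.with_suffix(".nodes.tsv")),
        provenance=f"{network}/{which}",
    )
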