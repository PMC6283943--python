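"""Bundled ecdysozoan visual-opsin fixture.

The package ships, as plain-text data files, the published summary of
ecdysozoan visual-opsin evolution: the four dated duplications of the
opsin family (with 95% credibility intervals from a relaxed-clock
analysis), the five divergence intervals along the arthropod stem
lineage (from a total-evidence, fossilised-birth-death timetree), a
compact species tree containing both fossil and extant ecdysozoan tips,
a gene tree summarising the paralogue distribution across phyla, and a
presence/absence table for the extant terminals.

Internal-node credibility intervals and the duplication intervals are
published values; point ages of unlabelled internal nodes and fossil tip
ages are representative placeholders chosen only to keep the tree
chronologically consistent — the inference consumes the intervals, not
the point ages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .dated_trees import AgeTableRow, CredibleInterval, DatedTree, parse_dated_tree, read_age_table
from .nomenclature import (
    DEFAULT_PRECEDENCE,
    DuplicationEvent,
    GeneLineageTree,
    build_gene_lineage_tree,
    read_duplication_events,
)
from .reconciliation import TipMap

__all__ = [
    "ecdysozoan_duplication_events",
    "ecdysozoan_gene_lineage_tree",
    "ecdysozoan_divergences",
    "ecdysozoan_fixture",
    "ecdysozoan_species_tree",
    "ecdysozoan_gene_tree",
    "ecdysozoan_tip_map",
    "ecdysozoan_presence",
    "data_path",
]

_PKG = "palaeopsin.data"


def data_path(name: str):
    """Filesystem path of a bundled data file (context-manager free for eager use)."""
    return resources.files(_PKG) / name


def ecdysozoan_duplication_events() -> list[DuplicationEvent]:
    """The four dated duplications of the ecdysozoan visual opsin family."""
    with (resources.files(_PKG) / "ecdysozoan_duplications.tsv").open() as fh:
        return read_duplication_events(fh)


def ecdysozoan_gene_lineage_tree() -> GeneLineageTree:
    """The named, dated opsin duplication chain (root: Rh7/UV/SWS/MWS/LWS)."""
    return build_gene_lineage_tree(ecdysozoan_duplication_events(), DEFAULT_PRECEDENCE)


def ecdysozoan_divergences() -> dict[str, CredibleInterval]:
    """The five published divergence intervals along the arthropod stem."""
    with (resources.files(_PKG) / "ecdysozoan_divergences.tsv").open() as fh:
        rows = read_age_table(fh)
    return {row.label: row.ci for row in rows}


def ecdysozoan_divergence_rows() -> list[AgeTableRow]:
    with (resources.files(_PKG) / "ecdysozoan_divergences.tsv").open() as fh:
        return read_age_table(fh)


def ecdysozoan_fixture() -> tuple[GeneLineageTree, dict[str, CredibleInterval]]:
    """(duplication chain, divergence-CI table) — the golden worked example."""
    return ecdysozoan_gene_lineage_tree(), ecdysozoan_divergences()


def ecdysozoan_species_tree() -> DatedTree:
    """Dated ecdysozoan species tree with fossil tips and focal-node CIs."""
    text = (resources.files(_PKG) / "ecdysozoan_species_tree.nwk").read_text()
    return parse_dated_tree(text, dialect="annotated")


def ecdysozoan_gene_tree() -> DatedTree:
    """Summary opsin gene tree (topology only; tips = species_paralogue)."""
    text = (resources.files(_PKG) / "ecdysozoan_gene_tree.nwk").read_text()
    return parse_dated_tree(text, dialect="bare")


def ecdysozoan_tip_map() -> TipMap:
    with (resources.files(_PKG) / "ecdysozoan_tip_map.tsv").open() as fh:
        return TipMap.from_tsv(fh)


def ecdysozoan_presence() -> dict[str, set[str]]:
    """Gene presence per extant terminal (semicolon-separated in the TSV)."""
    with (resources.files(_PKG) / "ecdysozoan_presence.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {
        str(rec["species"]): {g for g in str(rec["genes"]).split(";") if g}
        for rec in df.to_dict("records")
    }
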