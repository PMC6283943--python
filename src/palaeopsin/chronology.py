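"""Minimal ancestral gene complements from credibility-interval comparison.

The core inference: a gene duplication is judged to *precede* a species
divergence only when the divergence interval lies entirely more recent
than the duplication interval, i.e. when the old bound of the divergence
95% CI is strictly younger than the young bound of the duplication 95%
CI.  Any overlap — including exact boundary equality — is *ambiguous*,
and the descending lineage is conservatively assigned the ancestral,
pre-duplication gene rather than the daughter paralogues.  The inferred
complement of a stem lineage is therefore always minimal.

Walking the dated duplication chain with this rule yields a *frontier
cut*: starting from the root gene, a gene is expanded into its daughters
iff its duplication precedes the divergence; the unexpanded frontier is
the complement.

For clades whose sampled descendants are all extant, presence is instead
inferred by Dollo phylogenetic bracketing on a presence/absence table
(single origin at the MRCA of the possessing tips, any number of
losses).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dated_trees import CredibleInterval, DatedNode, DatedTree, mrca, resolve_node
from .errors import ChronologyError
from .nomenclature import (
    DEFAULT_PRECEDENCE,
    GeneLineageTree,
    GeneNode,
    NamePrecedence,
    split_name,
)

__all__ = [
    "PrecedenceVerdict",
    "precedes",
    "infer_complement",
    "infer_all",
    "bracket_extant",
    "chromacy",
    "ComplementRow",
    "ComplementTable",
    "VerdictRecord",
]


class PrecedenceVerdict(enum.Enum):
    """Outcome of one duplication-vs-divergence interval comparison.

    Ternary logic ("precedes / follows / unknown") is deliberately
    collapsed to two states: anything short of unambiguous precedence is
    treated as ambiguous, which is what makes the inferred complements
    minimal.
    """

    PRECEDES = "precedes"
    AMBIGUOUS = "ambiguous"


def precedes(dup: CredibleInterval, div: CredibleInterval) -> PrecedenceVerdict:
    """Did the duplication precede the divergence, at 95% credibility?

    ``PRECEDES`` iff ``div.old < dup.young`` (strict: the whole divergence
    interval is more recent than the whole duplication interval).  Equal
    endpoints count as overlap and hence ``AMBIGUOUS``.
    """
    if div.old < dup.young:
        return PrecedenceVerdict.PRECEDES
    return PrecedenceVerdict.AMBIGUOUS


@dataclass(frozen=True)
class VerdictRecord:
    """Audit record for one duplication considered during a frontier cut."""

    gene: str
    dup_ci: CredibleInterval
    div_ci: CredibleInterval
    verdict: PrecedenceVerdict
    expanded: bool


def infer_complement(
    glt: GeneLineageTree,
    div: CredibleInterval,
    audit: list[VerdictRecord] | None = None,
) -> set[str]:
    """Minimal gene set inherited by a lineage diverging in interval ``div``.

    Performs the frontier cut of the duplication chain: the root gene is
    expanded into its daughters iff its duplication precedes ``div``;
    daughters are then considered recursively.  A daughter duplication is
    never evaluated unless its parent was expanded, so the result is
    well-defined even if sampled CIs are not perfectly nested.
    """
    frontier: set[str] = set()

    def walk(node: GeneNode) -> None:
        if node.is_leaf:
            frontier.add(node.name)
            return
        verdict = precedes(node.ci, div)
        expand = verdict is PrecedenceVerdict.PRECEDES
        if audit is not None:
            audit.append(VerdictRecord(node.name, node.ci, div, verdict, expand))
        if expand:
            for child in node.children:
                walk(child)
        else:
            frontier.add(node.name)

    walk(glt.root)
    return frontier


def chromacy(
    complement: Iterable[str],
    rh7_nonvisual: bool = True,
) -> tuple[int, str]:
    """Number of visual pigment classes and the implied colour-vision class.

    The standalone ``Rh7`` gene is, by default, counted as non-visual
    (its characterised role is circadian entrainment); composite ancestral
    genes that merely *contain* Rh7 as a component (e.g. ``Rh7/UV/SWS``)
    still count as visual.  Classes: 0 → ``none``, 1 → ``monochromat``,
    2 → ``dichromat``, 3 → ``trichromat``, >3 → ``polychromat``.
    """
    genes = set(complement)
    n = len(genes)
    if rh7_nonvisual and any(split_name(g) == frozenset({"Rh7"}) for g in genes):
        n -= 1
    classes = {0: "none", 1: "monochromat", 2: "dichromat", 3: "trichromat"}
    return n, classes.get(n, "polychromat")


@dataclass
class ComplementRow:
    """One focal lineage of a :class:`ComplementTable`."""

    label: str
    div: CredibleInterval | None
    genes: tuple[str, ...]
    size: int
    visual_count: int
    chromacy_class: str
    audit: tuple[VerdictRecord, ...] = ()
    error: str | None = None
    method: str = "interval_comparison"


class ComplementTable:
    """Per-lineage inferred minimal gene complements."""

    def __init__(self, rows: Sequence[ComplementRow], precedence: NamePrecedence = DEFAULT_PRECEDENCE):
        self.rows = list(rows)
        self.precedence = precedence

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def __getitem__(self, label: str) -> ComplementRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    def sizes(self) -> dict[str, int]:
        return {row.label: row.size for row in self.rows if row.error is None}

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            recs.append(
                {
                    "lineage": row.label,
                    "div_ci_young": row.div.young if row.div else None,
                    "div_ci_old": row.div.old if row.div else None,
                    "genes": ";".join(row.genes),
                    "size": row.size,
                    "visual_count": row.visual_count,
                    "chromacy": row.chromacy_class,
                    "method": row.method,
                    "error": row.error,
                }
            )
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = []
        for row in self.rows:
            payload.append(
                {
                    "lineage": row.label,
                    "div_ci": [row.div.young, row.div.old] if row.div else None,
                    "genes": list(row.genes),
                    "size": row.size,
                    "visual_count": row.visual_count,
                    "chromacy": row.chromacy_class,
                    "method": row.method,
                    "error": row.error,
                    "audit": [
                        {
                            "gene": v.gene,
                            "dup_ci": [v.dup_ci.young, v.dup_ci.old],
                            "div_ci": [v.div_ci.young, v.div_ci.old],
                            "verdict": v.verdict.value,
                        }
                        for v in row.audit
                    ],
                }
            )
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def _make_row(
    label: str,
    glt: GeneLineageTree,
    div: CredibleInterval,
    rh7_nonvisual: bool,
) -> ComplementRow:
    audit: list[VerdictRecord] = []
    genes = infer_complement(glt, div, audit=audit)
    ordered = tuple(sorted(genes, key=lambda g: min(glt.precedence.rank(p) for p in split_name(g))))
    n_vis, cls = chromacy(genes, rh7_nonvisual=rh7_nonvisual)
    return ComplementRow(
        label=label,
        div=div,
        genes=ordered,
        size=len(genes),
        visual_count=n_vis,
        chromacy_class=cls,
        audit=tuple(audit),
    )


def infer_all(
    species_tree: DatedTree | None,
    glt: GeneLineageTree,
    foci: Iterable,
    rh7_nonvisual: bool = True,
) -> ComplementTable:
    """One complement row per focus, in input order.

    Each focus is either ``(label, CredibleInterval)`` — a pre-resolved
    divergence interval — or a node selector (label / node id / pair of
    tip labels) resolved against ``species_tree``, whose node must carry a
    CI.  A focus without a usable CI yields a row with ``error`` set; the
    run continues.
    """
    rows: list[ComplementRow] = []
    for focus in foci:
        label: str
        div: CredibleInterval | None = None
        err: str | None = None
        if (
            isinstance(focus, tuple)
            and len(focus) == 2
            and isinstance(focus[1], CredibleInterval)
        ):
            label, div = focus
        else:
            label = focus if isinstance(focus, str) else "+".join(map(str, focus))
            if species_tree is None:
                err = "no species tree supplied to resolve the focus against"
            else:
                try:
                    node = resolve_node(species_tree, focus)
                    if node.label:
                        label = node.label
                    if node.ci is None:
                        err = f"focus node {label!r} has no credibility interval"
                    else:
                        div = node.ci
                except ChronologyError as exc:
                    err = str(exc)
                except Exception as exc:  # selector resolution failures
                    err = str(exc)
        if err is not None or div is None:
            rows.append(
                ComplementRow(
                    label=label,
                    div=div,
                    genes=(),
                    size=0,
                    visual_count=0,
                    chromacy_class="none",
                    error=err or "no divergence interval",
                )
            )
            continue
        rows.append(_make_row(label, glt, div, rh7_nonvisual))
    return ComplementTable(rows, glt.precedence)


def bracket_extant(
    species_tree: DatedTree,
    presence: Mapping[str, Iterable[str]],
    node,
    known_genes: Iterable[str] | None = None,
) -> set[str]:
    """Dollo phylogenetic bracketing of gene presence at an extant-only node.

    ``presence`` maps extant tip labels to the gene names they carry.  A
    gene is inferred present at the node iff the node lies at or below the
    MRCA of all tips possessing it and at least one of the node's
    descendant tips possesses it (single origin, unlimited loss).  A tip
    carrying a derived paralogue also evidences every ancestral composite
    gene (``UV`` counts toward ``UV/SWS``: component sets are nested), and
    the returned set is the most-derived frontier — ancestral composites
    are dropped when one of their descendants is itself present.  Nodes
    with fossil descendants must be handled by interval comparison
    (:func:`infer_complement`) instead and raise :class:`ChronologyError`.
    """
    target = resolve_node(species_tree, node)
    fossil = [lf.label for lf in target.leaves() if lf.tip_kind == "fossil"]
    if fossil:
        raise ChronologyError(
            f"node has fossil descendants {fossil}; presence at such nodes must be "
            "inferred by divergence-time comparison (infer_complement), not bracketing"
        )
    if known_genes is not None:
        known = {split_name(g) for g in known_genes}
        for tip, genes in presence.items():
            for g in genes:
                if split_name(g) not in known:
                    raise ChronologyError(f"unknown gene name {g!r} on tip {tip!r}")

    under = {lf.label for lf in target.leaves()}
    all_genes: dict[frozenset[str], str] = {}
    carried: dict[str, set[frozenset[str]]] = {}
    for tip, genes in presence.items():
        if tip not in species_tree.taxon_index:
            raise ChronologyError(f"presence table names unknown tip {tip!r}")
        for g in genes:
            key = split_name(g)
            all_genes.setdefault(key, g)
            carried.setdefault(tip, set()).add(key)

    # a derived paralogue evidences every ancestral composite in the table
    possessors: dict[frozenset[str], set[str]] = {key: set() for key in all_genes}
    for tip, keys in carried.items():
        for key in all_genes:
            if any(k <= key for k in keys):
                possessors[key].add(tip)

    present_keys: set[frozenset[str]] = set()
    for key, tips in possessors.items():
        if not tips or not (tips & under):
            continue
        origin = mrca(species_tree, tips)
        if species_tree.is_ancestor(origin, target):
            present_keys.add(key)
    # report the most-derived frontier only
    frontier = {
        key for key in present_keys
        if not any(other < key for other in present_keys)
    }
    return {all_genes[key] for key in frontier}
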