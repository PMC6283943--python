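"""Parsimony (LCA) reconciliation of a gene tree with a species tree.

Each gene-tree node is mapped to the lowest species-tree node containing
all the species of its descendant gene copies.  A gene node is a
*duplication* when it maps to the same species node as at least one of
its children; otherwise it is a speciation.  This mapping attains the
parsimony minimum number of duplications and reproduces the placement of
duplications on a fixed rooted species topology — which is all the
downstream complement inference consumes.  Probabilistic, gene-tree-aware
reconciliation is deliberately out of scope.

Losses are not reconstructed explicitly: :func:`copies_at` counts only
gene lineages with surviving sampled descendants (Dollo-consistent), so
secondary loss in a sampled lineage shows up as reduced tip counts, not
as inferred loss events.  Multifurcations in either tree are handled by
the same LCA semantics without arbitrary binarisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .dated_trees import DatedNode, DatedTree, resolve_node
from .errors import ReconciliationError

__all__ = [
    "TipMap",
    "ReconciliationMap",
    "lca_reconcile",
    "copies_at",
    "copy_count_table",
    "EVENTS",
]

EVENTS = ("leaf", "speciation", "duplication")


@dataclass(frozen=True)
class TipMap:
    """Maps each gene-tree tip label to a (species label, copy id) pair."""

    mapping: Mapping[str, tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str] | tuple[str, str, str]]) -> "TipMap":
        out = {}
        for row in pairs:
            gene, species, *rest = row
            out[gene] = (species, rest[0] if rest else gene)
        return cls(out)

    @classmethod
    def from_tsv(cls, source) -> "TipMap":
        df = pd.read_csv(source, sep="\t", comment="#")
        needed = {"gene_tip", "species"}
        if not needed.issubset(df.columns):
            raise ReconciliationError(
                f"tip map needs columns {sorted(needed)}; got {list(df.columns)}"
            )
        out = {}
        for rec in df.to_dict("records"):
            copy_id = str(rec.get("copy_id", rec["gene_tip"]))
            out[str(rec["gene_tip"])] = (str(rec["species"]), copy_id)
        return cls(out)

    def to_tsv(self, path) -> None:
        rows = [
            {"gene_tip": g, "species": s, "copy_id": c}
            for g, (s, c) in self.mapping.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def species_of(self, gene_tip: str) -> str:
        try:
            return self.mapping[gene_tip][0]
        except KeyError:
            raise ReconciliationError(f"gene tip {gene_tip!r} missing from tip map") from None


class ReconciliationMap:
    """Per-gene-node mapping to species nodes with event labels."""

    def __init__(
        self,
        gene_tree: DatedTree,
        species_tree: DatedTree,
        node_map: Mapping[str, tuple[str, str]],
    ):
        self.gene_tree = gene_tree
        self.species_tree = species_tree
        self.node_map = dict(node_map)  # gene node id -> (species node id, event)

    def species_of(self, gene_node: DatedNode) -> DatedNode:
        return self.species_tree.node(self.node_map[gene_node.id][0])

    def event_of(self, gene_node: DatedNode) -> str:
        return self.node_map[gene_node.id][1]

    def duplications(self) -> list[DatedNode]:
        return [
            nd for nd in self.gene_tree.preorder() if self.node_map[nd.id][1] == "duplication"
        ]

    @property
    def duplication_count(self) -> int:
        return len(self.duplications())

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for nd in self.gene_tree.preorder():
            sid, event = self.node_map[nd.id]
            snode = self.species_tree.node(sid)
            recs.append(
                {
                    "gene_node": nd.id,
                    "gene_label": nd.label,
                    "species_node": sid,
                    "species_label": snode.label,
                    "event": event,
                }
            )
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _lca(a: DatedNode, b: DatedNode, depth: Mapping[int, int]) -> DatedNode:
    while a is not b:
        if depth[id(a)] >= depth[id(b)]:
            a = a.parent
        else:
            b = b.parent
    return a


def lca_reconcile(gene_tree: DatedTree, species_tree: DatedTree, tip_map: TipMap) -> ReconciliationMap:
    """Standard LCA (parsimony) reconciliation of rooted trees.

    Raises :class:`ReconciliationError` for unmapped gene tips or species
    labels absent from the species tree.
    """
    depth: dict[int, int] = {}
    for nd in species_tree.preorder():
        depth[id(nd)] = 0 if nd.parent is None else depth[id(nd.parent)] + 1

    mapping: dict[str, tuple[str, str]] = {}
    species_node: dict[str, DatedNode] = {}

    for nd in gene_tree.postorder():
        if nd.is_leaf:
            species_label = tip_map.species_of(nd.label)
            if species_label not in species_tree.taxon_index:
                raise ReconciliationError(
                    f"species {species_label!r} (gene tip {nd.label!r}) is absent "
                    "from the species tree"
                )
            snode = species_tree.taxon_index[species_label]
            species_node[nd.id] = snode
            mapping[nd.id] = (snode.id, "leaf")
        else:
            snode = species_node[nd.children[0].id]
            for child in nd.children[1:]:
                snode = _lca(snode, species_node[child.id], depth)
            event = (
                "duplication"
                if any(species_node[c.id] is snode for c in nd.children)
                else "speciation"
            )
            species_node[nd.id] = snode
            mapping[nd.id] = (snode.id, event)

    return ReconciliationMap(gene_tree, species_tree, mapping)


def copies_at(species_node, rec: ReconciliationMap, gene_tree: DatedTree | None = None) -> int:
    """Number of distinct gene lineages crossing the branch above a species node.

    A lineage counts when the reconciliation places its origin (the
    duplication that created it, or the family root) at or above the
    species node and it retains at least one sampled descendant copy at or
    below the node.  Under Dollo single-origin logic the family as a whole
    does not extend above the species node its root gene maps to.
    """
    if gene_tree is None:
        gene_tree = rec.gene_tree
    X = resolve_node(rec.species_tree, species_node) if not isinstance(species_node, DatedNode) else species_node
    if X.id not in rec.species_tree._by_id:
        raise ReconciliationError(f"node {X!r} is not part of the species tree")

    clade_ids = {nd.id for nd in X.preorder()}
    strict_anc_ids = {nd.id for nd in X.ancestors()}

    # does each gene subtree retain a sampled copy at/below X?
    has_copy_below: dict[str, bool] = {}
    for nd in gene_tree.postorder():
        if nd.is_leaf:
            has_copy_below[nd.id] = rec.species_of(nd).id in clade_ids
        else:
            has_copy_below[nd.id] = any(has_copy_below[c.id] for c in nd.children)

    root = gene_tree.root
    root_map = rec.species_of(root)
    if root_map.id in clade_ids and root_map.id != X.id:
        return 0  # family originated strictly below X

    def crossings(nd: DatedNode) -> int:
        if not has_copy_below[nd.id]:
            return 0
        m = rec.species_of(nd)
        if m.id in strict_anc_ids or (m.id == X.id and rec.event_of(nd) == "duplication"):
            # the event at nd happened above X (duplications mapped to X are
            # placed on the branch subtending X); descend into each daughter
            return sum(crossings(c) for c in nd.children)
        return 1

    return crossings(root)


def copy_count_table(rec: ReconciliationMap) -> pd.DataFrame:
    """Copies crossing into every internal species node (tips included)."""
    recs = []
    for nd in rec.species_tree.preorder():
        recs.append(
            {
                "species_node": nd.id,
                "species_label": nd.label,
                "tip_kind": nd.tip_kind,
                "copies": copies_at(nd, rec),
            }
        )
    return pd.DataFrame(recs)
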