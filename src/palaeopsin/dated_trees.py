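"""Rooted, dated phylogenies with credibility intervals and fossil tips.

Ages are expressed in Ma before present ("older" = numerically larger).
Internal nodes may carry a point age and/or a 95% credibility interval;
tips are *extant* (age 0) or *fossil* (age > 0), mirroring the dated
tip-calibrated timetrees produced by Bayesian total-evidence dating.

Three input dialects are supported:

``annotated``
    Newick/NEXUS with BEAST/FigTree-style node comments of the form
    ``[&age=571.3,ci={558,585}]``.  Interval endpoints may be written in
    either order; they are normalised so that ``young <= old``.
``branch_lengths``
    Bare Newick with branch lengths plus a declared root age; node ages
    are obtained by subtracting root-to-node path lengths from the root
    age.
``bare``
    Topology only; ages can be attached later with
    :func:`attach_node_ages`.

All Newick/NEXUS syntax handling is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import AgeTableError, TreeParseError, TreeValidationError

__all__ = [
    "CredibleInterval",
    "DatedNode",
    "DatedTree",
    "AgeTableRow",
    "parse_dated_tree",
    "write_dated_tree",
    "attach_node_ages",
    "mrca",
    "resolve_node",
    "read_age_table",
    "DIALECTS",
]

DIALECTS = ("annotated", "branch_lengths", "bare")

_AGE_TOL = 1e-9


@dataclass(frozen=True)
class CredibleInterval:
    """A 95% (by default) credibility interval on an event age, in Ma BP.

    ``young`` is the more recent bound (smaller number), ``old`` the more
    ancient one.  Degenerate intervals (``young == old``) are permitted and
    arise from zero-noise simulations.
    """

    young: float
    old: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.young <= self.old):
            raise TreeValidationError(
                f"invalid credibility interval ({self.young}, {self.old}): "
                "need 0 <= young <= old"
            )

    @classmethod
    def of(cls, a: float, b: float) -> "CredibleInterval":
        """Build an interval from two bounds in either order."""
        a, b = float(a), float(b)
        return cls(min(a, b), max(a, b))

    @property
    def width(self) -> float:
        return self.old - self.young

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.young + self.old)

    def contains(self, age: float) -> bool:
        return self.young - _AGE_TOL <= age <= self.old + _AGE_TOL

    def overlaps(self, other: "CredibleInterval") -> bool:
        return self.young <= other.old and other.young <= self.old

    def approx_equals(self, other: "CredibleInterval", tol: float = 1e-6) -> bool:
        return (
            math.isclose(self.young, other.young, rel_tol=tol, abs_tol=tol)
            and math.isclose(self.old, other.old, rel_tol=tol, abs_tol=tol)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.young:g}–{self.old:g} Ma)"


class DatedNode:
    """A node of a :class:`DatedTree`.

    Attributes
    ----------
    id : str
        Opaque identifier, unique within the tree (assigned in preorder if
        not set explicitly).
    label : str or None
        Tip name, or an optional clade name for internal nodes.
    age : float or None
        Point age in Ma before present.
    ci : CredibleInterval or None
    branch_length : float or None
        Length of the branch subtending this node, retained so that trees
        parsed without ages round-trip unchanged.
    """

    __slots__ = ("id", "label", "age", "ci", "branch_length", "children", "parent")

    def __init__(
        self,
        label: str | None = None,
        age: float | None = None,
        ci: CredibleInterval | None = None,
        children: Sequence["DatedNode"] | None = None,
        branch_length: float | None = None,
        id: str | None = None,
    ) -> None:
        self.id = id
        self.label = label
        self.age = age
        self.ci = ci
        self.branch_length = branch_length
        self.children: list[DatedNode] = list(children or [])
        self.parent: DatedNode | None = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def tip_kind(self) -> str:
        """``extant`` / ``fossil`` for tips, ``internal`` otherwise."""
        if self.children:
            return "internal"
        if self.age is not None and self.age > _AGE_TOL:
            return "fossil"
        return "extant"

    def add_child(self, node: "DatedNode") -> "DatedNode":
        node.parent = self
        self.children.append(node)
        return node

    def preorder(self) -> Iterator["DatedNode"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator["DatedNode"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["DatedNode"]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def ancestors(self, include_self: bool = False) -> Iterator["DatedNode"]:
        nd = self if include_self else self.parent
        while nd is not None:
            yield nd
            nd = nd.parent

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DatedNode(id={self.id!r}, label={self.label!r}, age={self.age!r})"


class DatedTree:
    """A rooted tree of :class:`DatedNode` with a tip-label index."""

    def __init__(self, root: DatedNode, validate: bool = True) -> None:
        self.root = root
        self._assign_ids()
        self.taxon_index: dict[str, DatedNode] = {}
        for leaf in root.leaves():
            if leaf.label is None:
                raise TreeValidationError(f"unlabelled tip (id={leaf.id})")
            if leaf.label in self.taxon_index:
                raise TreeValidationError(f"duplicate tip label {leaf.label!r}")
            self.taxon_index[leaf.label] = leaf
        self._by_id = {nd.id: nd for nd in root.preorder()}
        if validate:
            self.validate()

    def _assign_ids(self) -> None:
        seen: set[str] = set()
        counter = 0
        for nd in self.root.preorder():
            if nd.id is None:
                while f"n{counter}" in seen:
                    counter += 1
                nd.id = f"n{counter}"
                counter += 1
            if nd.id in seen:
                raise TreeValidationError(f"duplicate node id {nd.id!r}")
            seen.add(nd.id)

    # -- queries ---------------------------------------------------------

    def node(self, node_id: str) -> DatedNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise TreeValidationError(f"no node with id {node_id!r}") from None

    def tip(self, label: str) -> DatedNode:
        try:
            return self.taxon_index[label]
        except KeyError:
            raise TreeValidationError(f"unknown tip label {label!r}") from None

    def preorder(self) -> Iterator[DatedNode]:
        return self.root.preorder()

    def postorder(self) -> Iterator[DatedNode]:
        return self.root.postorder()

    def leaves(self) -> list[DatedNode]:
        return self.root.leaves()

    def internal_nodes(self) -> list[DatedNode]:
        return [nd for nd in self.preorder() if not nd.is_leaf]

    def mrca(self, labels: Iterable[str]) -> DatedNode:
        return mrca(self, labels)

    def leaf_labels_under(self, node: DatedNode) -> frozenset[str]:
        return frozenset(leaf.label for leaf in node.leaves())

    def is_ancestor(self, anc: DatedNode, desc: DatedNode) -> bool:
        """True if ``anc`` is an ancestor of (or equal to) ``desc``."""
        return any(nd is anc for nd in desc.ancestors(include_self=True))

    def copy(self) -> "DatedTree":
        # explicit iterative clone: parent back-links make deepcopy recurse
        # far deeper than the tree height
        clones: dict[int, DatedNode] = {}
        for nd in self.preorder():
            clone = DatedNode(
                label=nd.label,
                age=nd.age,
                ci=nd.ci,
                branch_length=nd.branch_length,
                id=nd.id,
            )
            clones[id(nd)] = clone
            if nd.parent is not None:
                clones[id(nd.parent)].add_child(clone)
        return DatedTree(clones[id(self.root)], validate=False)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for nd in self.preorder():
            if len(nd.children) == 1:
                raise TreeValidationError(
                    f"internal node {nd.id} has a single child; rooted trees "
                    "must be at least bifurcating"
                )
            if nd.age is not None and nd.age < -_AGE_TOL:
                raise TreeValidationError(f"negative age at node {nd.id}: {nd.age}")
            if nd.age is not None and nd.ci is not None and not nd.ci.contains(nd.age):
                raise TreeValidationError(
                    f"node {nd.id}: point age {nd.age} outside its interval {nd.ci}"
                )
            if nd.age is not None:
                for child in nd.children:
                    if child.age is not None and child.age > nd.age + _AGE_TOL:
                        raise TreeValidationError(
                            "age monotonicity violated: parent "
                            f"{nd.id} ({nd.age} Ma) younger than child "
                            f"{child.id} ({child.age} Ma)"
                        )

    # -- comparison ------------------------------------------------------

    def approx_equals(self, other: "DatedTree", tol: float = 1e-6) -> bool:
        """Equality of topology, labels, ages and intervals (within tol)."""

        def eq(a: DatedNode, b: DatedNode) -> bool:
            if a.label != b.label or len(a.children) != len(b.children):
                return False
            if (a.age is None) != (b.age is None):
                return False
            if a.age is not None and not math.isclose(
                a.age, b.age, rel_tol=tol, abs_tol=tol
            ):
                return False
            if (a.ci is None) != (b.ci is None):
                return False
            if a.ci is not None and not a.ci.approx_equals(b.ci, tol):
                return False
            return all(eq(ca, cb) for ca, cb in zip(a.children, b.children))

        return eq(self.root, other.root)

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DatedTree({len(self.leaves())} tips, {len(self)} nodes)"


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

_NUM = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"
_CI_RE = re.compile(r"ci\s*=\s*\{(" + _NUM + r")\s*,\s*(" + _NUM + r")\}")
_AGE_RE = re.compile(r"age\s*=\s*(" + _NUM + r")")


def _annotation_values(nd: dendropy.Node) -> tuple[float | None, CredibleInterval | None]:
    age: float | None = None
    ci: CredibleInterval | None = None
    for ann in nd.annotations:
        if ann.name == "age":
            age = float(ann.value)
        elif ann.name == "ci":
            lo, hi = (float(v) for v in ann.value)
            ci = CredibleInterval.of(lo, hi)
    # fall back to raw comment text if metadata extraction missed them
    if age is None or ci is None:
        for comment in nd.comments:
            if age is None:
                m = _AGE_RE.search(comment)
                if m:
                    age = float(m.group(1))
            if ci is None:
                m = _CI_RE.search(comment)
                if m:
                    ci = CredibleInterval.of(float(m.group(1)), float(m.group(2)))
    return age, ci


def parse_dated_tree(
    text: str,
    dialect: str = "annotated",
    schema: str = "newick",
    root_age: float | None = None,
) -> DatedTree:
    """Parse Newick/NEXUS text into a :class:`DatedTree`.

    Parameters
    ----------
    text : str
        The tree string.
    dialect : {"annotated", "branch_lengths", "bare"}
        How node ages are conveyed (see module docstring).
    schema : {"newick", "nexus"}
        Serialisation syntax, passed through to dendropy.
    root_age : float, optional
        Required for the ``branch_lengths`` dialect: the age of the root in
        Ma before present.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "branch_lengths" and root_age is None:
        raise ValueError("dialect 'branch_lengths' requires a declared root_age")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        offset = ""
        for attr in ("col_num", "column"):
            col = getattr(exc, attr, None)
            if col is not None:
                offset = f" (near character {col}"
                line = getattr(exc, "line_num", None)
                offset += f" of line {line})" if line is not None else ")"
                break
        raise TreeParseError(f"malformed {schema} tree{offset}: {exc}") from exc

    def convert(dnd: dendropy.Node) -> DatedNode:
        label = dnd.taxon.label if dnd.taxon is not None else dnd.label
        node = DatedNode(label=label, branch_length=dnd.edge.length)
        if dialect == "annotated":
            node.age, node.ci = _annotation_values(dnd)
        for child in dnd.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)

    if dialect == "branch_lengths":
        def set_ages(nd: DatedNode, depth: float) -> None:
            age = root_age - depth
            if age < -1e-6:
                raise TreeValidationError(
                    f"node {nd.label or '<internal>'} lies {-age:g} Ma below the "
                    f"present under declared root age {root_age}"
                )
            nd.age = 0.0 if abs(age) < 1e-6 else age
            for child in nd.children:
                if child.branch_length is None:
                    raise TreeValidationError(
                        "dialect 'branch_lengths' requires a branch length on "
                        f"every edge; missing above {child.label or 'an internal node'}"
                    )
                set_ages(child, depth + child.branch_length)

        set_ages(root, 0.0)

    if dialect in ("annotated", "bare"):
        # tips without an explicit age are extant by convention
        for nd in root.preorder():
            if nd.is_leaf and nd.age is None:
                nd.age = 0.0

    return DatedTree(root)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_dated_tree(tree: DatedTree, dialect: str = "annotated", schema: str = "newick") -> str:
    """Serialise a :class:`DatedTree`; output reparses to an equal tree."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def convert(nd: DatedNode) -> dendropy.Node:
        dnd = dendropy.Node()
        if nd.is_leaf:
            dnd.taxon = taxa.require_taxon(label=nd.label)
        elif nd.label:
            dnd.label = nd.label
        if nd.parent is not None:
            if nd.age is not None and nd.parent.age is not None:
                dnd.edge.length = nd.parent.age - nd.age
            else:
                dnd.edge.length = nd.branch_length
        if dialect == "annotated":
            parts = []
            if nd.age is not None:
                parts.append(f"age={_fmt(nd.age)}")
            if nd.ci is not None:
                parts.append(f"ci={{{_fmt(nd.ci.young)},{_fmt(nd.ci.old)}}}")
            if parts:
                dnd.comments.append("&" + ",".join(parts))
        for child in nd.children:
            dnd.add_child(convert(child))
        return dnd

    dtree.seed_node = convert(tree.root)
    text = dtree.as_string(
        schema=schema,
        suppress_rooting=(schema == "newick"),
        suppress_item_comments=False,
    )
    return text


# ---------------------------------------------------------------------------
# MRCA and node selection
# ---------------------------------------------------------------------------


def mrca(tree: DatedTree, tips: Iterable[str]) -> DatedNode:
    """Lowest common ancestor of a set of tip labels."""
    labels = list(tips)
    if not labels:
        raise TreeValidationError("mrca of an empty tip set is undefined")
    nodes = [tree.tip(lab) for lab in labels]
    common: set[int] | None = None
    for nd in nodes:
        anc_ids = {id(a) for a in nd.ancestors(include_self=True)}
        common = anc_ids if common is None else (common & anc_ids)
    # deepest node among the common ancestors = the one with no child in the set
    nd = nodes[0]
    for a in nd.ancestors(include_self=True):
        if id(a) in common:
            return a
    raise TreeValidationError("trees is disconnected; no common ancestor found")


def resolve_node(tree: DatedTree, selector) -> DatedNode:
    """Resolve a focus selector to a node.

    Accepts a node id or clade/tip label (``str``), or a pair of tip labels
    whose MRCA is taken (the same addressing used by the age table).
    """
    if isinstance(selector, DatedNode):
        return selector
    if isinstance(selector, str):
        if selector in tree.taxon_index:
            return tree.taxon_index[selector]
        for nd in tree.preorder():
            if nd.label == selector:
                return nd
        try:
            return tree.node(selector)
        except TreeValidationError:
            raise TreeValidationError(
                f"selector {selector!r} matches no tip, clade label or node id"
            ) from None
    try:
        a, b = selector
    except (TypeError, ValueError):
        raise TreeValidationError(f"cannot interpret node selector {selector!r}") from None
    if a == b:
        raise TreeValidationError("MRCA selector requires two distinct tips")
    return mrca(tree, [a, b])


# ---------------------------------------------------------------------------
# sidecar age tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeTableRow:
    """One row of a sidecar node-age table, addressing the MRCA of two tips."""

    tip_a: str
    tip_b: str
    age: float | None = None
    ci: CredibleInterval | None = None
    label: str | None = None


def read_age_table(source) -> list[AgeTableRow]:
    """Read a TSV with columns tip_a, tip_b, age, ci_young, ci_old [, label]."""
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"tip_a", "tip_b"}
    if not required.issubset(df.columns):
        raise AgeTableError(f"age table needs columns {sorted(required)}; got {list(df.columns)}")
    rows = []
    for rec in df.to_dict("records"):
        ci = None
        if "ci_young" in rec and not pd.isna(rec.get("ci_young")):
            ci = CredibleInterval.of(float(rec["ci_young"]), float(rec["ci_old"]))
        age = None
        if "age" in rec and not pd.isna(rec.get("age")):
            age = float(rec["age"])
        rows.append(
            AgeTableRow(
                tip_a=str(rec["tip_a"]),
                tip_b=str(rec["tip_b"]),
                age=age,
                ci=ci,
                label=(str(rec["label"]) if "label" in rec and not pd.isna(rec.get("label")) else None),
            )
        )
    return rows


def attach_node_ages(tree: DatedTree, rows: Iterable[AgeTableRow | tuple]) -> DatedTree:
    """Attach ages/CIs from a sidecar table to MRCA nodes of a copied tree.

    Rows addressing the same node must agree (idempotent re-assignment is
    fine); conflicting assignments and monotonicity violations raise
    :class:`AgeTableError`.  Topology is never modified.
    """
    out = tree.copy()
    assigned: dict[str, AgeTableRow] = {}
    for raw in rows:
        row = raw if isinstance(raw, AgeTableRow) else AgeTableRow(*raw)
        if row.tip_a == row.tip_b:
            raise AgeTableError(
                f"row ({row.tip_a!r}, {row.tip_b!r}): two distinct tips are required"
            )
        try:
            node = mrca(out, [row.tip_a, row.tip_b])
        except TreeValidationError as exc:
            raise AgeTableError(str(exc)) from exc
        prev = assigned.get(node.id)
        if prev is not None:
            same_age = (prev.age is None and row.age is None) or (
                prev.age is not None
                and row.age is not None
                and math.isclose(prev.age, row.age, rel_tol=1e-9, abs_tol=1e-9)
            )
            same_ci = (prev.ci is None and row.ci is None) or (
                prev.ci is not None and row.ci is not None and prev.ci.approx_equals(row.ci)
            )
            if not (same_age and same_ci):
                raise AgeTableError(
                    f"conflicting assignments for the MRCA of ({row.tip_a}, {row.tip_b}): "
                    f"{prev} vs {row}"
                )
            continue
        assigned[node.id] = row
        if row.age is not None:
            node.age = row.age
        if row.ci is not None:
            node.ci = row.ci
        if row.label is not None and not node.is_leaf:
            node.label = row.label
    try:
        out.validate()
    except TreeValidationError as exc:
        raise AgeTableError(f"age table violates tree chronology: {exc}") from exc
    return out
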