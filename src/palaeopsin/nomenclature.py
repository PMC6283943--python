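"""Canonical naming of ancestral genes and the dated duplication chain.

A pre-duplication (ancestral) gene is named by concatenating, with
slashes, the names of the terminal paralogues that descend from it, in a
fixed precedence order — e.g. the ancestor of the arthropod visual opsins
is the ``Rh7/UV/SWS/MWS/LWS`` opsin, and the ancestor of the two
long-wave paralogues is ``MWS/LWS``.  Because published texts sometimes
permute the components, name identity is defined on the *set* of
components, not on the string (:func:`same_gene`).

The :class:`GeneLineageTree` is the dated duplication history itself: a
rooted tree whose leaves are terminal paralogues and whose internal nodes
are duplication events, each carrying the credibility interval of the
event that splits that gene into its two daughters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .dated_trees import CredibleInterval
from .errors import NomenclatureError

__all__ = [
    "NamePrecedence",
    "DEFAULT_PRECEDENCE",
    "canonical_name",
    "split_name",
    "same_gene",
    "DuplicationEvent",
    "GeneNode",
    "GeneLineageTree",
    "build_gene_lineage_tree",
    "read_duplication_events",
    "write_duplication_events",
]


def split_name(name: str) -> frozenset[str]:
    """Decompose a (possibly concatenated) gene name into its components."""
    return frozenset(part for part in name.split("/") if part)


def same_gene(a: str, b: str) -> bool:
    """Name equality on the underlying component set (order-insensitive)."""
    return split_name(a) == split_name(b)


class NamePrecedence:
    """A total order over terminal paralogue names fixing concatenation order."""

    def __init__(self, order: Sequence[str]):
        order = list(order)
        if len(set(order)) != len(order):
            raise NomenclatureError(f"precedence list has repeated names: {order}")
        self.order = tuple(order)
        self._rank = {name: i for i, name in enumerate(order)}

    def rank(self, name: str) -> int:
        try:
            return self._rank[name]
        except KeyError:
            raise NomenclatureError(
                f"unknown terminal paralogue name {name!r}; known: {list(self.order)}"
            ) from None

    def sort(self, names: Iterable[str]) -> list[str]:
        return sorted(names, key=self.rank)

    def __contains__(self, name: str) -> bool:
        return name in self._rank

    def __iter__(self):
        return iter(self.order)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NamePrecedence({list(self.order)})"


#: Order used throughout for the ecdysozoan visual opsins.
DEFAULT_PRECEDENCE = NamePrecedence(["Rh7", "UV", "SWS", "MWS", "LWS"])


def canonical_name(leaf_names: Iterable[str], precedence: NamePrecedence = DEFAULT_PRECEDENCE) -> str:
    """Slash-joined concatenation of ``leaf_names`` in precedence order.

    A singleton set returns the bare terminal name.
    """
    names = set(leaf_names)
    if not names:
        raise NomenclatureError("cannot name a gene with no terminal descendants")
    return "/".join(precedence.sort(names))


@dataclass(frozen=True)
class DuplicationEvent:
    """A duplication splitting a gene into two daughter paralogue sets."""

    left: frozenset[str]
    right: frozenset[str]
    ci: CredibleInterval

    def __post_init__(self):
        if not self.left or not self.right:
            raise NomenclatureError("duplication event with an empty daughter set")
        if self.left & self.right:
            raise NomenclatureError(
                f"duplication daughters overlap: {sorted(self.left)} / {sorted(self.right)}"
            )

    @property
    def block(self) -> frozenset[str]:
        return self.left | self.right


class GeneNode:
    """A node of the gene lineage tree.

    Internal nodes carry the CI of the duplication that splits them; leaves
    are terminal paralogues (or composite genes never observed to split).
    """

    __slots__ = ("name", "leaves", "ci", "children", "parent")

    def __init__(self, name, leaves, ci=None, children=()):
        self.name: str = name
        self.leaves: frozenset[str] = frozenset(leaves)
        self.ci: CredibleInterval | None = ci
        self.children: tuple[GeneNode, ...] = tuple(children)
        self.parent: GeneNode | None = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["GeneNode"]:
        stack = [self]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneNode({self.name!r}, ci={self.ci})"


class GeneLineageTree:
    """The dated duplication chain over a set of terminal paralogues."""

    def __init__(self, root: GeneNode, precedence: NamePrecedence = DEFAULT_PRECEDENCE):
        self.root = root
        self.precedence = precedence
        self.validate()

    # -- queries ---------------------------------------------------------

    def preorder(self) -> Iterator[GeneNode]:
        return self.root.preorder()

    def duplications(self) -> list[GeneNode]:
        return [nd for nd in self.preorder() if not nd.is_leaf]

    def terminals(self) -> list[GeneNode]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def find(self, name: str) -> GeneNode:
        target = split_name(name)
        for nd in self.preorder():
            if split_name(nd.name) == target:
                return nd
        raise NomenclatureError(f"no gene named {name!r} in the lineage tree")

    @property
    def n_duplications(self) -> int:
        return len(self.duplications())

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for nd in self.preorder():
            derived = frozenset().union(*(c.leaves for c in nd.children)) if nd.children else nd.leaves
            if nd.leaves != derived:
                raise NomenclatureError(
                    f"gene {nd.name!r}: leaf set {sorted(nd.leaves)} does not match "
                    f"its descendants {sorted(derived)}"
                )
            expected = canonical_name(nd.leaves, self.precedence)
            if not same_gene(nd.name, expected):
                raise NomenclatureError(
                    f"gene name {nd.name!r} is not canonical (expected {expected!r})"
                )
            if not nd.is_leaf and nd.ci is None:
                raise NomenclatureError(f"duplication {nd.name!r} lacks an age interval")
            if not nd.is_leaf and nd.parent is not None and nd.parent.ci is not None:
                parent = nd.parent
                if nd.ci.old > parent.ci.old + 1e-9 or nd.ci.young > parent.ci.old + 1e-9:
                    raise NomenclatureError(
                        "duplication ages not monotone: "
                        f"{nd.name!r} {nd.ci} is older than its parent "
                        f"{parent.name!r} {parent.ci}"
                    )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneLineageTree(root={self.root.name!r}, duplications={self.n_duplications})"


def build_gene_lineage_tree(
    dup_events: Iterable[DuplicationEvent | tuple],
    precedence: NamePrecedence = DEFAULT_PRECEDENCE,
    terminals: Iterable[str] | None = None,
) -> GeneLineageTree:
    """Assemble the unique :class:`GeneLineageTree` realising nested events.

    ``dup_events`` may be :class:`DuplicationEvent` objects or
    ``(left_names, right_names, ci)`` tuples.  The events must form a
    laminar (hierarchically nested) family; input order is irrelevant.
    With no events, a single-gene history over ``terminals`` is returned.
    """
    events: list[DuplicationEvent] = []
    for ev in dup_events:
        if not isinstance(ev, DuplicationEvent):
            left, right, ci = ev
            if not isinstance(ci, CredibleInterval):
                ci = CredibleInterval.of(*ci)
            ev = DuplicationEvent(frozenset(left), frozenset(right), ci)
        events.append(ev)

    for name in {n for ev in events for n in ev.block}:
        precedence.rank(name)  # raises on unknown terminals

    if not events:
        terms = list(terminals or [])
        if len(terms) != 1:
            raise NomenclatureError(
                "a history without duplications needs exactly one terminal gene"
            )
        return GeneLineageTree(GeneNode(terms[0], [terms[0]]), precedence)

    by_block: dict[frozenset[str], DuplicationEvent] = {}
    for ev in events:
        if ev.block in by_block and by_block[ev.block] is not ev:
            raise NomenclatureError(
                f"two duplication events split the same gene {canonical_name(ev.block, precedence)!r}"
            )
        by_block[ev.block] = ev

    all_leaves = frozenset().union(*(ev.block for ev in events))
    used: set[frozenset[str]] = set()

    def build(block: frozenset[str]) -> GeneNode:
        ev = by_block.get(block)
        name = canonical_name(block, precedence)
        if ev is None:
            return GeneNode(name, block)
        used.add(block)
        return GeneNode(name, block, ci=ev.ci, children=(build(ev.left), build(ev.right)))

    root = build(all_leaves)
    unused = set(by_block) - used
    if unused:
        names = sorted(canonical_name(b, precedence) for b in unused)
        raise NomenclatureError(
            f"duplication events are not hierarchically nested; unreachable blocks: {names}"
        )
    return GeneLineageTree(root, precedence)


# ---------------------------------------------------------------------------
# TSV / JSON interchange
# ---------------------------------------------------------------------------


def read_duplication_events(source) -> list[DuplicationEvent]:
    """Read events from TSV (leaves_left, leaves_right, ci_young, ci_old) or JSON."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    text_stripped = text.lstrip()
    records: list[dict]
    if text_stripped.startswith("[") or text_stripped.startswith("{"):
        records = json.loads(text)
        if isinstance(records, dict):
            records = records["events"]
    else:
        import io

        df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
        records = df.to_dict("records")
    events = []
    for rec in records:
        left = [s.strip() for s in str(rec["leaves_left"]).split(",")]
        right = [s.strip() for s in str(rec["leaves_right"]).split(",")]
        ci = CredibleInterval.of(float(rec["ci_young"]), float(rec["ci_old"]))
        events.append(DuplicationEvent(frozenset(left), frozenset(right), ci))
    return events


def write_duplication_events(events: Iterable[DuplicationEvent], path, precedence: NamePrecedence = DEFAULT_PRECEDENCE) -> None:
    rows = [
        {
            "leaves_left": ",".join(precedence.sort(ev.left)),
            "leaves_right": ",".join(precedence.sort(ev.right)),
            "ci_young": ev.ci.young,
            "ci_old": ev.ci.old,
        }
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
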