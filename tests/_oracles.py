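"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the algorithms under test: the MRCA oracle
intersects explicit ancestor paths; the reconciliation oracle enumerates
*every* valid gene→species mapping and takes the minimum duplication
count; the frontier oracle cuts the duplication chain by direct time
comparison instead of the recursive frontier walk.
"""

from __future__ import annotations

from palaeopsin.dated_trees import DatedNode, DatedTree


def mrca_bruteforce(tree: DatedTree, labels) -> DatedNode:
    """MRCA as the deepest node in the intersection of root-ward paths."""
    paths = []
    for lab in labels:
        nd = tree.tip(lab)
        paths.append(list(nd.ancestors(include_self=True)))
    common = set(id(n) for n in paths[0])
    for p in paths[1:]:
        common &= {id(n) for n in p}
    for nd in paths[0]:  # ordered tip -> root, first common hit is deepest
        if id(nd) in common:
            return nd
    raise AssertionError("no common ancestor")


def _subtree_ids(node: DatedNode) -> frozenset[int]:
    return frozenset(id(nd) for nd in node.preorder())


def min_duplications_bruteforce(gene_tree: DatedTree, species_tree: DatedTree, tip_map) -> int:
    """Minimum duplications over an exhaustive enumeration of valid mappings.

    A mapping is valid when every gene node maps to a species node that is
    an ancestor of (or equal to) each child's image.  A binary gene node
    is a speciation iff its two children's images lie in *distinct* child
    subtrees of its own image; otherwise it is a duplication.
    """
    sp_nodes = list(species_tree.preorder())
    ancestors = {
        id(nd): [a for a in nd.ancestors(include_self=True)] for nd in sp_nodes
    }
    child_subtrees = {id(nd): [_subtree_ids(c) for c in nd.children] for nd in sp_nodes}

    gene_post = list(gene_tree.postorder())
    leaf_image = {}
    for nd in gene_post:
        if nd.is_leaf:
            leaf_image[id(nd)] = species_tree.taxon_index[tip_map.species_of(nd.label)]

    def lca(a: DatedNode, b: DatedNode) -> DatedNode:
        bs = {id(x) for x in ancestors[id(b)]}
        for x in ancestors[id(a)]:
            if id(x) in bs:
                return x
        raise AssertionError("disconnected species tree")

    internal = [nd for nd in gene_post if not nd.is_leaf]
    best = [len(internal) + 1]

    def is_duplication(image: DatedNode, child_images) -> bool:
        subtrees = child_subtrees[id(image)]
        taken: set[int] = set()
        for ci in child_images:
            slot = None
            for k, ids in enumerate(subtrees):
                if k not in taken and id(ci) in ids:
                    slot = k
                    break
            if slot is None:
                return True
            taken.add(slot)
        return False

    def assign(i: int, images: dict[int, DatedNode], dups: int) -> None:
        if dups >= best[0]:
            return
        if i == len(internal):
            best[0] = dups
            return
        nd = internal[i]
        child_images = [
            leaf_image[id(c)] if c.is_leaf else images[id(c)] for c in nd.children
        ]
        low = child_images[0]
        for ci in child_images[1:]:
            low = lca(low, ci)
        for candidate in ancestors[id(low)]:  # low, then every ancestor
            images[id(nd)] = candidate
            d = 1 if is_duplication(candidate, child_images) else 0
            assign(i + 1, images, dups + d)
        del images[id(nd)]

    assign(0, {}, 0)
    return best[0]


def frontier_by_time_cut(glt, div_time: float) -> set[str]:
    """Genes existing immediately after a divergence at ``div_time``.

    Direct formulation on degenerate (true-time) chains: a gene is on the
    frontier iff every ancestral duplication is strictly older than the
    divergence while its own duplication (if any) is not.
    """
    out = set()
    for nd in glt.preorder():
        anc_ok = True
        p = nd.parent
        while p is not None:
            if not (p.ci.young > div_time):
                anc_ok = False
                break
            p = p.parent
        if not anc_ok:
            continue
        if nd.is_leaf or not (nd.ci.young > div_time):
            out.add(nd.name)
    return out
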