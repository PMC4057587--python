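"""Neighbor-joining reconstruction and tree accuracy metrics.

Trees are ``dendropy.Tree`` objects throughout: leaf nodes carry taxa,
edges carry real branch lengths, and an unrooted tree is represented
with a degree-3 seed node (the usual convention for binary unrooted
trees).

Three operations assess how well a distance matrix recovers a known
phylogeny or classification:

* :func:`neighbor_joining` — standard Q-criterion agglomeration; exact
  on additive matrices, deterministic tie-breaking.
* :func:`rf_symmetric_difference` — the Robinson–Foulds symmetric
  difference: the number of nontrivial bipartitions (internal edges)
  present in exactly one of two trees on the same leaf set.
* :func:`parsimony_score` — a leaf-label parsimony count: leaves are
  labeled by their true groups and a bottom-up pass assigns each
  internal node the intersection of its children's label sets if it is
  nonempty, otherwise their union at a penalty of one.  A tree in which
  every group is monophyletic scores (number of groups - 1).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "root_with_outgroup",
    "rf_symmetric_difference",
    "parsimony_score",
    "enumerate_bipartitions",
    "leaf_labels",
]


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    """Set of leaf taxon labels of a tree."""
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _min_leaf(node: dendropy.Node) -> str:
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def neighbor_joining(
    d: DistanceMatrix, clamp_negative: bool = False
) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Standard agglomeration: at each step the pair (i, j) minimizing
    Q(i, j) = (m - 2) d(i, j) - r(i) - r(j) is joined, with r the row
    sums over the m active clusters.  Ties are broken by the
    lexicographically smallest pair of cluster representatives (the
    smallest leaf label in each cluster), so the output is
    deterministic.  On an additive matrix the unique generating
    topology and its branch lengths are recovered.

    Negative branch lengths (which NJ can produce on non-additive
    input) are retained unless ``clamp_negative`` is set.

    Returns an unrooted tree: the seed node has degree 3.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(d.labels)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for label in d.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
        reps.append(label)

    D = d.values.astype(float).copy()
    active = list(range(n))

    def _length(value: float) -> float:
        return max(0.0, value) if clamp_negative else value

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        # minimize over the upper triangle only: q[i,j] and q[j,i] can
        # differ in the last ulp (summation order), and the tie-break
        # must see each pair exactly once
        iu = np.triu_indices(m, k=1)
        qmin = q[iu].min()
        best: Optional[tuple[str, str, int, int]] = None
        for ai, aj in zip(*iu):
            if q[ai, aj] == qmin:
                key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                if best is None or key < best[:2]:
                    best = (*key, int(ai), int(aj))
        assert best is not None
        ai, aj = best[2], best[3]
        i, j = active[ai], active[aj]

        d_ij = sub[ai, aj]
        li = 0.5 * d_ij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = d_ij - li

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _length(li)
        nodes[j].edge.length = _length(lj)

        # distances from the new cluster to the remaining ones
        new_row = np.zeros(D.shape[0] + 1)
        for ak in range(m):
            if ak in (ai, aj):
                continue
            k = active[ak]
            new_row[k] = 0.5 * (sub[ai, ak] + sub[aj, ak] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :] = new_row
        D[:, -1] = new_row
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final three-way join: branch lengths from the three-point formulas
    i, j, k = active
    d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
    center = dendropy.Node()
    for idx, length in (
        (i, 0.5 * (d_ij + d_ik - d_jk)),
        (j, 0.5 * (d_ij + d_jk - d_ik)),
        (k, 0.5 * (d_ik + d_jk - d_ij)),
    ):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = _length(length)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def enumerate_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial leaf-set bipartitions of a tree, one per internal edge.

    Each bipartition is canonicalized to the side *not* containing the
    smallest leaf label, so bipartition sets of different trees on the
    same leaf set are directly comparable.  An unrooted binary tree on
    n leaves yields exactly n - 3 bipartitions; a star tree yields
    none.  For rooted trees the root edge is ignored (the two sides of
    the root describe the same split).
    """
    all_labels = leaf_labels(tree)
    if len(all_labels) < 4:
        return set()
    ref = min(all_labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) < 2 or len(all_labels) - len(side) < 2:
            continue
        if ref in side:
            side = frozenset(all_labels - side)
        out.add(side)
    return out


def rf_symmetric_difference(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric difference between two trees.

    The number of nontrivial bipartitions present in one tree but not
    the other, summed over both directions (the convention of PHYLIP
    ``treedist``; always even when both trees are binary).
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            "trees have different leaf sets: "
            f"{sorted(l1 ^ l2)} not shared"
        )
    return len(enumerate_bipartitions(t1) ^ enumerate_bipartitions(t2))


def root_with_outgroup(
    tree: dendropy.Tree, outgroup: Iterable[str]
) -> dendropy.Tree:
    """Root a tree at the midpoint of the edge separating an outgroup.

    If no single edge splits the outgroup exactly from the ingroup,
    the edge whose bipartition disagrees with the outgroup on the
    fewest leaves is used.  The input tree is not modified.
    """
    outgroup = set(outgroup)
    leaves = leaf_labels(tree)
    if not outgroup:
        raise ValueError("outgroup is empty")
    if outgroup == leaves:
        raise ValueError("outgroup cannot contain every leaf")
    unknown = outgroup - leaves
    if unknown:
        raise ValueError(f"outgroup labels not in tree: {sorted(unknown)}")

    rooted = tree.clone(depth=1)
    best_edge = None
    best_score = None
    for node in rooted.preorder_node_iter():
        if node is rooted.seed_node:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if not side or side == leaves:
            continue
        mismatch = min(len(side ^ outgroup), len((leaves - side) ^ outgroup))
        if best_score is None or mismatch < best_score:
            best_score = mismatch
            best_edge = node.edge
    assert best_edge is not None
    length = best_edge.length
    half = None if length is None else length / 2.0
    rooted.reroot_at_edge(best_edge, length1=half, length2=half)
    rooted.is_rooted = True
    return rooted


def parsimony_score(
    tree: dendropy.Tree, groups: Mapping[str, str]
) -> int:
    """Leaf-label parsimony score of a tree against a true classification.

    The score starts at 0 and each leaf is labeled with its group.
    Traversing from the leaves toward the root, an internal node takes
    the common labels of its children when any exist; when the children
    share no label, a penalty of 1 is added and the node takes the
    union of their labels.  Multifurcations (including the degree-3
    seed of an unrooted tree) fold their children in sequentially with
    the same rule; the score is invariant to where an unrooted tree is
    rooted.  A tree in which every group is monophyletic scores
    (number of groups - 1).
    """
    unlabeled = sorted(leaf_labels(tree) - set(groups))
    if unlabeled:
        raise ValueError(f"leaves missing from the label map: {unlabeled}")
    score = 0
    node_sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_sets[node] = frozenset((groups[node.taxon.label],))
            continue
        current: Optional[frozenset[str]] = None
        for child in node.child_nodes():
            child_set = node_sets.pop(child)
            if current is None:
                current = child_set
            else:
                shared = current & child_set
                if shared:
                    current = shared
                else:
                    score += 1
                    current = current | child_set
        assert current is not None
        node_sets[node] = current
    return score
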