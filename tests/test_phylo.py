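"""Neighbor joining, bipartitions, Robinson–Foulds, and parsimony,
cross-checked against brute force and independent implementations."""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

import compdist as cd
from compdist.distances import DistanceMatrix
from compdist.phylo import (
    enumerate_bipartitions,
    leaf_labels,
    neighbor_joining,
    parsimony_score,
    rf_symmetric_difference,
    root_with_outgroup,
)


def newick(s: str, tns=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=s, schema="newick", taxon_namespace=tns, preserve_underscores=True
    )


def _edge_lengths(tree):
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        key = frozenset(l.taxon.label for l in node.leaf_iter())
        out[key] = node.edge.length
    return out


def _patristic_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(tax[a], tax[labels[j]])
    return m


class TestNeighborJoining:
    def test_additive_four_taxa(self):
        # pendant edges a:1 b:2 c:3 d:4, internal edge 1
        labels = ["a", "b", "c", "d"]
        values = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, values))
        assert enumerate_bipartitions(tree) == {frozenset({"c", "d"})}
        lengths = _edge_lengths(tree)
        for leaf, expected in zip("abcd", (1, 2, 3, 4)):
            assert lengths[frozenset({leaf})] == pytest.approx(expected)
        internal = [
            v for k, v in lengths.items() if len(k) == 2
        ]
        assert internal == [pytest.approx(1.0)]

    def test_three_taxa_three_point_formulas(self):
        labels = ["a", "b", "c"]
        values = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, values))
        lengths = _edge_lengths(tree)
        assert lengths[frozenset({"a"})] == pytest.approx(1.0)
        assert lengths[frozenset({"b"})] == pytest.approx(2.0)
        assert lengths[frozenset({"c"})] == pytest.approx(4.0)

    def test_zero_distance_pair_become_siblings(self):
        labels = ["a", "b", "c", "d"]
        values = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, values))
        assert frozenset({"c", "d"}) in enumerate_bipartitions(tree)

    def test_too_few_taxa_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_consistency_on_random_additive_matrices(self, rng):
        # topology and branch lengths are recovered exactly from
        # path-length matrices of random trees
        for trial in range(20):
            n = int(rng.integers(5, 12))
            labels = [f"t{i:02d}" for i in range(n)]
            guide = cd.random_tree(
                labels, seed=int(rng.integers(2**31)), branch_length_range=(0.05, 1.0)
            )
            d = DistanceMatrix(labels, _patristic_matrix(guide, labels))
            assert rf_symmetric_difference(neighbor_joining(d), guide) == 0

    def test_agrees_with_skbio_on_generic_matrix(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        n = 8
        labels = [f"t{i}" for i in range(n)]
        m = rng.uniform(0.2, 1.0, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        mine = neighbor_joining(DistanceMatrix(labels, m))
        other = newick(str(sk_nj(SkDM(m, ids=labels))).strip())
        assert rf_symmetric_difference(mine, other) == 0

    def test_clamp_negative_option(self, rng):
        n = 6
        labels = [f"t{i}" for i in range(n)]
        m = rng.uniform(0.1, 1.0, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        clamped = neighbor_joining(DistanceMatrix(labels, m), clamp_negative=True)
        for node in clamped.preorder_node_iter():
            if node is not clamped.seed_node:
                assert node.edge.length >= 0


class TestBipartitions:
    def test_counts(self):
        assert len(enumerate_bipartitions(newick("((a,b),(c,d));"))) == 1
        eight = newick("(((a,b),(c,d)),((e,f),(g,h)));")
        assert len(enumerate_bipartitions(eight)) == 5
        assert enumerate_bipartitions(newick("(a,b,c,d,e);")) == set()

    def test_canonical_sides_comparable_across_trees(self):
        t1 = newick("((a,b),(c,d),e);")
        t2 = newick("(e,(c,d),(a,b));")
        assert enumerate_bipartitions(t1) == enumerate_bipartitions(t2)


class TestSymmetricDifference:
    def test_identical_trees(self):
        t = newick("((a,b),(c,d),e);")
        assert rf_symmetric_difference(t, t) == 0

    def test_five_leaf_example(self):
        t1 = newick("((a,b),(c,d),e);")
        t2 = newick("((a,c),(b,d),e);")
        assert rf_symmetric_difference(t1, t2) == 4

    def test_nearest_neighbor_interchange(self):
        t1 = newick("(((a,b),c),(d,(e,f)));")
        t2 = newick("(((a,c),b),(d,(e,f)));")
        assert rf_symmetric_difference(t1, t2) == 2

    def test_leaf_set_mismatch_raises(self):
        with pytest.raises(ValueError, match="leaf sets"):
            rf_symmetric_difference(newick("((a,b),(c,d));"), newick("((a,b),(c,e));"))

    def test_matches_dendropy_on_random_trees(self, rng):
        tns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        from dendropy.calculate import treecompare

        for trial in range(25):
            t1 = cd.random_tree([f"t{i}" for i in range(8)], seed=int(rng.integers(2**31)))
            t2 = cd.random_tree([f"t{i}" for i in range(8)], seed=int(rng.integers(2**31)))
            a = newick(t1.as_string(schema="newick"), tns)
            b = newick(t2.as_string(schema="newick"), tns)
            # compare in the unrooted sense, as treedist does
            for t in (a, b):
                t.is_rooted = False
                t.update_bipartitions()
            assert rf_symmetric_difference(t1, t2) == treecompare.symmetric_difference(a, b)

    def test_is_a_metric_on_binary_trees(self, rng):
        labels = [f"t{i}" for i in range(8)]
        for trial in range(10):
            seeds = rng.integers(2**31, size=3)
            t1, t2, t3 = (cd.random_tree(labels, seed=int(s)) for s in seeds)
            d12 = rf_symmetric_difference(t1, t2)
            d13 = rf_symmetric_difference(t1, t3)
            d23 = rf_symmetric_difference(t2, t3)
            assert d12 == rf_symmetric_difference(t2, t1)
            assert d12 >= 0
            assert d13 <= d12 + d23


class TestOutgroupRooting:
    def test_single_leaf_outgroup(self):
        tree = neighbor_joining(
            DistanceMatrix(
                ["a", "b", "c", "d"],
                np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
            )
        )
        rooted = root_with_outgroup(tree, {"a"})
        assert rooted.is_rooted
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = {
            frozenset(l.taxon.label for l in c.leaf_iter()) for c in children
        }
        assert frozenset({"a"}) in sides
        assert frozenset({"b", "c", "d"}) in sides

    def test_clade_outgroup_roots_on_internal_edge(self):
        tree = neighbor_joining(
            DistanceMatrix(
                ["a", "b", "c", "d"],
                np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
            )
        )
        rooted = root_with_outgroup(tree, {"c", "d"})
        sides = {
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        }
        assert sides == {frozenset({"c", "d"}), frozenset({"a", "b"})}

    def test_midpoint_split_of_edge_length(self):
        tree = neighbor_joining(
            DistanceMatrix(
                ["a", "b", "c", "d"],
                np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
            )
        )
        rooted = root_with_outgroup(tree, {"c", "d"})
        lengths = sorted(c.edge.length for c in rooted.seed_node.child_nodes())
        assert lengths == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_invalid_outgroups_raise(self):
        t = newick("((a,b),(c,d),e);")
        with pytest.raises(ValueError):
            root_with_outgroup(t, set())
        with pytest.raises(ValueError):
            root_with_outgroup(t, {"a", "b", "c", "d", "e"})
        with pytest.raises(ValueError, match="not in tree"):
            root_with_outgroup(t, {"z"})

    def test_input_tree_unchanged(self):
        t = newick("((a,b),(c,d),e);")
        before = t.as_string(schema="newick")
        root_with_outgroup(t, {"e"})
        assert t.as_string(schema="newick") == before


def _all_rooted_trees(leaves: tuple[str, ...]):
    """Every rooted binary topology over the given leaves (as newick)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(len(rest) + 1):
        for subset in itertools.combinations(rest, k):
            left = (first, *subset)
            right = tuple(l for l in rest if l not in subset)
            if not right:
                continue
            for lt in _all_rooted_trees(left):
                for rt in _all_rooted_trees(right):
                    yield f"({lt},{rt})"


def _sankoff_score(tree: dendropy.Tree, groups: dict[str, str]) -> int:
    """Independent small-parsimony oracle: unit-cost Sankoff DP."""
    states = sorted(set(groups.values()))
    big = 10**6
    costs = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            g = groups[node.taxon.label]
            costs[node] = [0 if s == g else big for s in states]
        else:
            total = [0] * len(states)
            for child in node.child_nodes():
                child_cost = costs[child]
                best = min(child_cost)
                for i in range(len(states)):
                    total[i] += min(child_cost[i], best + 1)
            costs[node] = total
    return min(costs[tree.seed_node])


class TestParsimonyScore:
    def _perfect_tree(self, group_sizes: dict[str, int]) -> tuple[dendropy.Tree, dict]:
        def ladder(labels):
            s = labels[0]
            for l in labels[1:]:
                s = f"({s},{l})"
            return s

        groups = {}
        clades = []
        for g, size in group_sizes.items():
            labels = [f"{g}_{i}" for i in range(size)]
            for l in labels:
                groups[l] = g
            clades.append(ladder(labels))
        return newick(ladder(clades) + ";"), groups

    def test_perfect_fifteen_groups_scores_fourteen(self):
        tree, groups = self._perfect_tree({f"g{i:02d}": 2 for i in range(15)})
        assert parsimony_score(tree, groups) == 14

    def test_perfect_three_groups_scores_two(self):
        tree, groups = self._perfect_tree({"fore": 13, "hind": 8, "carn": 7})
        assert parsimony_score(tree, groups) == 2

    def test_perfect_four_groups_scores_three(self):
        tree, groups = self._perfect_tree({"a": 5, "b": 4, "c": 3, "d": 2})
        assert parsimony_score(tree, groups) == 3

    def test_interleaved_cherries(self):
        tree = newick("((A1,B1),(A2,B2));")
        groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        assert parsimony_score(tree, groups) == 2

    def test_unlabeled_leaf_raises(self):
        tree = newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="missing"):
            parsimony_score(tree, {"a": "x", "b": "x", "c": "y"})

    @staticmethod
    def _is_convex(tree: dendropy.Tree, groups: dict[str, str]) -> bool:
        """True when the groups' spanning subtrees are vertex-disjoint.

        A leaf coloring can be explained with g - 1 changes exactly
        when each group occupies its own connected region of the tree
        (convexity, i.e. unrooted monophyly of every group).
        """
        import networkx as nx

        graph = nx.Graph()
        names = {}
        for i, node in enumerate(tree.preorder_node_iter()):
            names[node] = node.taxon.label if node.is_leaf() else f"__int{i}"
        for node in tree.preorder_node_iter():
            for child in node.child_nodes():
                graph.add_edge(names[node], names[child])
        spans = []
        for grp in set(groups.values()):
            members = [l for l, x in groups.items() if x == grp]
            vertices = set(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    vertices |= set(nx.shortest_path(graph, members[i], members[j]))
            # the rooted seed may lie on a path artificially when it has
            # degree 2; contract it out of consideration
            spans.append(vertices - {names[tree.seed_node]}
                         if len(tree.seed_node.child_nodes()) == 2
                         else vertices)
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                if spans[i] & spans[j]:
                    return False
        return True

    def test_bounds_and_monophyly_small_trees(self):
        # exhaustive over all rooted topologies on 5 leaves and a set
        # of 2- and 3-group labelings: g-1 <= score <= n-1, equality
        # at g-1 exactly when every group occupies its own connected
        # region of the tree
        leaves = ("l1", "l2", "l3", "l4", "l5")
        labelings = [
            {"l1": "x", "l2": "x", "l3": "x", "l4": "y", "l5": "y"},
            {"l1": "x", "l2": "y", "l3": "x", "l4": "y", "l5": "x"},
            {"l1": "x", "l2": "y", "l3": "z", "l4": "z", "l5": "x"},
        ]
        for nwk in _all_rooted_trees(leaves):
            tree = newick(nwk + ";")
            for groups in labelings:
                g = len(set(groups.values()))
                score = parsimony_score(tree, groups)
                assert g - 1 <= score <= len(leaves) - 1
                assert (score == g - 1) == self._is_convex(tree, groups)

    def test_matches_sankoff_oracle(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 8))
            labels = [f"t{i}" for i in range(n)]
            tree = cd.random_tree(labels, seed=int(rng.integers(2**31)))
            groups = {l: f"g{rng.integers(3)}" for l in labels}
            if len(set(groups.values())) < 2:
                continue
            assert parsimony_score(tree, groups) == _sankoff_score(tree, groups)

    def test_root_invariance(self, rng):
        # the score does not depend on where an unrooted tree is rooted
        labels = [f"t{i}" for i in range(8)]
        guide = cd.random_tree(labels, seed=99)
        d = DistanceMatrix(labels, _patristic_matrix(guide, labels))
        unrooted = neighbor_joining(d)
        groups = {l: f"g{i % 3}" for i, l in enumerate(sorted(labels))}
        reference = parsimony_score(unrooted, groups)
        edges = [
            node.edge
            for node in unrooted.preorder_node_iter()
            if node is not unrooted.seed_node
        ]
        for edge in edges:
            clone = unrooted.clone(depth=1)
            # find the corresponding edge in the clone by leaf set
            target = frozenset(
                l.taxon.label for l in edge.head_node.leaf_iter()
            )
            for node in clone.preorder_node_iter():
                if node is clone.seed_node:
                    continue
                if frozenset(l.taxon.label for l in node.leaf_iter()) == target:
                    clone.reroot_at_edge(node.edge)
                    break
            assert parsimony_score(clone, groups) == reference


class TestNewickDeterminism:
    def test_write_read_write_stable(self, tmp_path, rng):
        from compdist.io import newick_string, read_newick, write_newick

        labels = [f"t{i}" for i in range(7)]
        tree = cd.random_tree(labels, seed=5)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert rf_symmetric_difference(tree, back) == 0
        assert newick_string(back) == newick_string(tree)
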