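import numpy as np
import pytest

from hoxmap.annotations import AnnotatedSequence
from hoxmap.njtree import (
    DistanceMatrix,
    TreeNode,
    InferredTree,
    attraction_check,
    domain_distance,
    neighbor_joining,
    p_distance,
)

from oracles import (
    best_topology_by_least_squares,
    canonical_splits,
    random_additive_tree,
)


class TestDistanceMatrix:
    def test_asymmetry_is_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], d)

    def test_nonzero_diagonal_is_rejected(self):
        d = np.array([[0.1, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], d)


class TestDomainDistance:
    def test_identical_domains_have_zero_distance(self, scenario, calibrated_profile):
        s = scenario.sequences[0]
        twin = AnnotatedSequence("twin", s.residues)
        dm = domain_distance([s, twin], calibrated_profile)
        assert dm.d[0, 1] == 0.0

    def test_six_of_sixty_mismatches_give_point_one(self, scenario, calibrated_profile):
        s = scenario.sequences[0]
        start, end = scenario.domain_spans[s.seq_id]
        res = list(s.residues)
        changed = 0
        for pos in range(start, end):
            if changed == 6:
                break
            res[pos] = "W" if res[pos] != "W" else "Y"
            changed += 1
        mutant = AnnotatedSequence("mut", "".join(res))
        dm = domain_distance([s, mutant], calibrated_profile)
        assert dm.d[0, 1] == pytest.approx(6 / 60)

    def test_sequence_without_domain_is_named_in_the_error(self, calibrated_profile):
        bald = AnnotatedSequence("no_domain", "MKVLW" * 20)
        with pytest.raises(ValueError, match="no_domain"):
            domain_distance([bald], calibrated_profile)

    def test_p_distance_may_violate_the_triangle_inequality(self):
        # documented property of the statistic, not an error
        a, b, c = "AAAA", "CCAA", "CCCC"
        assert p_distance(a, c) <= p_distance(a, b) + p_distance(b, c)
        # saturated corrected distances, in contrast, can blow up; p stays in [0,1]
        assert 0.0 <= p_distance(a, c) <= 1.0


def _additive_from(tree_dists):
    labels = sorted({x for pair in tree_dists for x in pair})
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in tree_dists.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_three_taxa_closed_form_branch_lengths(self):
        dm = _additive_from({("a", "b"): 0.6, ("a", "c"): 0.8, ("b", "c"): 1.0})
        tree = neighbor_joining(dm)
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.2)
        assert lengths["b"] == pytest.approx(0.4)
        assert lengths["c"] == pytest.approx(0.6)

    def test_four_taxon_additive_matrix_recovers_the_topology(self):
        # tree ((a,b),(c,d)) with internal branch 0.4
        dm = _additive_from({
            ("a", "b"): 0.4, ("c", "d"): 0.6,
            ("a", "c"): 1.0, ("a", "d"): 1.1, ("b", "c"): 1.0, ("b", "d"): 1.1,
        })
        tree = neighbor_joining(dm)
        splits = canonical_splits(tree.bipartitions(), dm.labels)
        oracle = best_topology_by_least_squares(dm.labels, dm.d)
        assert splits == oracle
        assert frozenset({"a", "b"}) in splits

    def test_ultrametric_five_taxon_hierarchy_is_recovered(self):
        # ((a,b),(c,(d,e))) ultrametric heights
        dm = _additive_from({
            ("a", "b"): 0.2,
            ("d", "e"): 0.2, ("c", "d"): 0.6, ("c", "e"): 0.6,
            ("a", "c"): 1.0, ("a", "d"): 1.0, ("a", "e"): 1.0,
            ("b", "c"): 1.0, ("b", "d"): 1.0, ("b", "e"): 1.0,
        })
        tree = neighbor_joining(dm)
        splits = canonical_splits(tree.bipartitions(), dm.labels)
        assert frozenset({"a", "b"}) in splits
        assert frozenset({"d", "e"}) in splits

    def test_fewer_than_three_taxa_is_an_error(self):
        dm = _additive_from({("a", "b"): 1.0})
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_invariant_under_label_order_permutation(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(6)]
        D, true_splits = random_additive_tree(labels, rng)
        t1 = neighbor_joining(DistanceMatrix(labels, D))
        perm = list(rng.permutation(6))
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(labels2, D2))
        assert canonical_splits(t1.bipartitions(), labels) == canonical_splits(
            t2.bipartitions(), labels
        )

    def test_agrees_with_skbio_on_additive_matrices(self):
        """Independent library cross-check (dendropy RF distance == 0)."""
        import dendropy
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        labels = [f"t{i}" for i in range(7)]
        for _ in range(5):
            D, _splits = random_additive_tree(labels, rng)
            mine = neighbor_joining(DistanceMatrix(labels, D))
            theirs = skbio_nj(SkbioDM(D, ids=labels))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=mine.newick, schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(d1, d2) == 0

    def test_negative_branches_clamp_to_zero_by_default(self):
        # a matrix engineered to produce a negative NJ branch
        d = np.array([
            [0.0, 0.1, 0.4, 0.45],
            [0.1, 0.0, 0.45, 0.4],
            [0.4, 0.45, 0.0, 0.1],
            [0.45, 0.4, 0.1, 0.0],
        ])
        tree = neighbor_joining(DistanceMatrix(list("abcd"), d))

        def all_lengths(node):
            yield node.length
            for c in node.children:
                yield from all_lengths(c)

        assert all(l >= 0 for l in all_lengths(tree.root))


class TestAttractionCheck:
    def _tree(self, newick_like):
        return newick_like

    def test_exclusive_neighborhood_is_detected(self):
        # ((a1,a2),(b1,b2),(c1,c2)): side {a*,b*} excludes c
        ab = TreeNode(children=[
            TreeNode(children=[TreeNode(label="a1"), TreeNode(label="a2")]),
            TreeNode(children=[TreeNode(label="b1"), TreeNode(label="b2")]),
        ])
        root = TreeNode(children=[
            ab, TreeNode(children=[TreeNode(label="c1"), TreeNode(label="c2")]),
            TreeNode(label="out"),
        ])
        tree = InferredTree(root, ["a1", "a2", "b1", "b2", "c1", "c2", "out"])
        res = attraction_check(tree, {"a1", "a2"}, {"b1", "b2"})
        assert res.attracted and res.extras == frozenset()

    def test_intermixed_caterpillar_is_not_attracted(self):
        # caterpillar a1,b1,a2,b2,c1,c2 -- a/b never exclusive
        node = TreeNode(children=[TreeNode(label="c1"), TreeNode(label="c2")])
        for leaf in ("b2", "a2", "b1"):
            node = TreeNode(children=[TreeNode(label=leaf), node])
        root = TreeNode(children=[TreeNode(label="a1"), node,
                                  TreeNode(label="x")])
        tree = InferredTree(root, ["a1", "b1", "a2", "b2", "c1", "c2", "x"])
        res = attraction_check(tree, {"a1", "a2"}, {"b1", "b2"})
        assert not res.attracted
        assert res.extras  # the smallest covering clade carries foreigners

    def test_input_validation(self):
        root = TreeNode(children=[TreeNode(label=l) for l in "abcd"])
        tree = InferredTree(root, list("abcd"))
        with pytest.raises(ValueError, match="disjoint"):
            attraction_check(tree, {"a", "b"}, {"b", "c"})
        with pytest.raises(ValueError, match="at least 2"):
            attraction_check(tree, {"a"}, {"b", "c"})
        with pytest.raises(ValueError, match="unknown"):
            attraction_check(tree, {"a", "z"}, {"b", "c"})
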