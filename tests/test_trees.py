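import numpy as np
import pytest

from phylodiscord import (
    NewickParseError,
    Split,
    TreeSample,
    ValidationError,
    extract_splits,
    is_monophyletic,
    majority_consensus,
    parse_newick,
    prune,
    resolve_polytomies,
    sim_tree,
    write_newick,
)
from oracles import count_clade_frequencies


class TestParseWrite:
    def test_minimal_two_leaf(self):
        t = parse_newick("(A,B);")
        assert t.leaves == {"A", "B"}
        assert write_newick(t) == "(A,B);"

    def test_lengths_and_support_read_off(self):
        t = parse_newick("((A:0.1,B:0.2)0.98:0.05,C:0.3);")
        inner = t.root.children[0]
        assert inner.support == 0.98
        assert inner.length == 0.05
        assert [c.length for c in inner.children] == [0.1, 0.2]
        assert ")0.98" in write_newick(t)

    @pytest.mark.parametrize(
        "bad",
        ["(A,B)", "((A,B);", "(A,(B);", "(A,B))C;", "(A,B)[&rate=1];", "(A,A);"],
    )
    def test_malformed_or_invalid_rejected(self, bad):
        with pytest.raises((NewickParseError, ValidationError)):
            parse_newick(bad)

    def test_nonnumeric_internal_label_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A,B)cladeX,C);")

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_random_trees(self, seed):
        t = sim_tree(3 + seed % 12, seed)
        rng = np.random.default_rng(seed)
        for node in t.postorder():
            if not node.is_leaf and node.parent is not None:
                node.support = round(float(rng.uniform()), 3)
        back = parse_newick(write_newick(t))
        assert back.signature() == t.signature()
        assert write_newick(back) == write_newick(t)


class TestExtractSplits:
    def test_resolved_quartet(self):
        t = parse_newick("((A,B)1.0,(C,D)1.0);")
        splits = extract_splits(t, 0.95)
        # the root's two child edges are one and the same AB|CD split
        assert len(splits) == 1
        (split,) = splits
        assert split.clade_side in (frozenset("AB"), frozenset("CD"))
        assert {split.side_a, split.side_b} == {frozenset("AB"), frozenset("CD")}

    def test_star_tree_has_no_internal_edges(self):
        assert extract_splits(parse_newick("(A,B,C,D,E);"), 0.0) == set()

    def test_caterpillar_six_leaves(self, caterpillar6):
        splits = extract_splits(caterpillar6, 0.95)
        assert len(splits) == 3  # AB, ABC, ABCD are non-trivial; ABCDE is not

    def test_unlabeled_edges_need_sentinel(self):
        t = parse_newick("((A,B),(C,D));")
        assert extract_splits(t, 0.0) == set()
        assert len(extract_splits(t, None)) == 1

    def test_splits_within_a_tree_are_pairwise_compatible(self):
        from phylodiscord import splits_conflict

        t = sim_tree(12, 7)
        for node in t.postorder():
            if not node.is_leaf:
                node.support = 1.0
        splits = list(extract_splits(t, None))
        assert len(splits) <= sum(1 for n in t.postorder() if not n.is_leaf)
        for i, a in enumerate(splits):
            for b in splits[i + 1:]:
                assert not splits_conflict(a, b)

    def test_fewer_than_three_leaves(self):
        assert extract_splits(parse_newick("(A,B);"), 0.0) == set()


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = parse_newick("((A,B),(C,D));")
        cons = majority_consensus(TreeSample([t.copy(), t.copy(), t.copy()]))
        supports = [
            n.support for n in cons.postorder()
            if not n.is_leaf and n is not cons.root
        ]
        assert supports and all(s == 1.0 for s in supports)

    def test_frequency_point_six(self):
        a = parse_newick("((A,B),C,D);")
        b = parse_newick("((A,C),B,D);")
        sample = TreeSample([a.copy() for _ in range(6)] + [b.copy() for _ in range(4)])
        cons = majority_consensus(sample, 0.5)
        ab_nodes = [
            n for n, clade in cons.clades() if clade == frozenset("AB")
        ]
        assert len(ab_nodes) == 1 and ab_nodes[0].support == pytest.approx(0.6)
        assert not any(clade == frozenset("AC") for _n, clade in cons.clades())

    def test_unanimity_cutoff_keeps_only_shared_splits(self):
        a = parse_newick("(((A,B),C),(D,E));")
        b = parse_newick("(((A,C),B),(D,E));")
        cons = majority_consensus(TreeSample([a, b]), 1.0)
        clades = {clade for _n, clade in cons.clades(include_leaves=False)}
        assert frozenset("DE") in clades
        assert frozenset("AB") not in clades and frozenset("AC") not in clades

    def test_supports_equal_counted_frequencies(self):
        sample = TreeSample([sim_tree(8, seed) for seed in range(11)])
        freqs = count_clade_frequencies(sample)
        cons = majority_consensus(sample, 0.5)
        seen = 0
        for node, clade in cons.clades(include_leaves=False):
            if node is cons.root:
                continue
            assert node.support == pytest.approx(freqs[clade])
            assert freqs[clade] > 0.5
            seen += 1
        # and nothing above the cutoff was dropped
        assert seen == sum(1 for f in freqs.values() if f > 0.5)

    def test_matches_dendropy_majority_rule(self):
        import dendropy

        trees = [sim_tree(7, seed) for seed in range(9)]
        cons = majority_consensus(TreeSample(trees), 0.5)
        tl = dendropy.TreeList.get(
            data="".join(write_newick(t) + "\n" for t in trees),
            schema="newick",
        )
        dcons = tl.consensus(min_freq=0.5)
        dclades = set()
        for node in dcons.preorder_node_iter():
            taxa = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(taxa) < 7:
                dclades.add(taxa)
        ours = {
            c
            for n, c in cons.clades(include_leaves=False)
            if n is not cons.root
        }
        assert ours == dclades

    def test_mixed_leaf_sets_rejected(self):
        with pytest.raises(ValidationError):
            TreeSample([parse_newick("(A,B,C);"), parse_newick("(A,B,D);")])

    def test_bad_cutoff(self):
        sample = TreeSample([parse_newick("(A,B,C);")])
        with pytest.raises(ValidationError):
            majority_consensus(sample, 0.4)


class TestPrune:
    def test_to_cherry(self, four_leaf_tree):
        t = prune(four_leaf_tree, {"A", "C"})
        assert t.leaves == {"A", "C"}
        assert len(t.root.children) == 2

    def test_lengths_sum_across_suppressed_nodes(self):
        t = parse_newick("(((A:0.1,B:0.4)0.9:0.2,C:0.5)0.8:0.3,D:1.0);")
        p = prune(t, {"A", "C", "D"})
        a = next(n for n in p.postorder() if n.name == "A")
        # A's pendant edge absorbs the suppressed (A,B) node: 0.1 + 0.2
        assert a.length == pytest.approx(0.3)

    def test_support_of_edge_closest_to_leaves_kept(self):
        t = parse_newick("(((A:1,B:1)0.7:1,C:1)0.9:1,(D:1,E:1)0.8:1);")
        p = prune(t, {"A", "B", "D", "E"})
        ab = next(
            n for n, c in p.clades() if c == frozenset("AB")
        )
        assert ab.support == 0.7

    def test_identity_and_idempotence(self, four_leaf_tree):
        full = prune(four_leaf_tree, four_leaf_tree.leaves)
        assert full.signature() == four_leaf_tree.signature()
        once = prune(four_leaf_tree, {"A", "B", "C"})
        twice = prune(once, {"A", "B", "C"})
        assert once.signature() == twice.signature()

    def test_missing_taxa_listed(self, four_leaf_tree):
        with pytest.raises(ValidationError, match="X.*Y|\\['X', 'Y'\\]"):
            prune(four_leaf_tree, {"A", "X", "Y"})

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_preserves_induced_splits(self, seed):
        t = sim_tree(8, seed)
        for node in t.postorder():
            if not node.is_leaf:
                node.support = 1.0
        keep = sorted(t.leaves)[: 5 + seed % 3]
        pruned = prune(t, keep)
        got = {
            (s.side_a, s.universe) for s in extract_splits(pruned, None)
        }
        expected = set()
        for s in extract_splits(t, None):
            r = s.restrict(keep)
            if r is not None:
                expected.add((r.side_a, r.universe))
        assert got == expected


class TestResolvePolytomies:
    def test_left_to_right_rule(self):
        t = resolve_polytomies(parse_newick("(A,B,C);"))
        assert write_newick(t) == "((A,B):0,C);"

    def test_binary_tree_unchanged(self, four_leaf_tree):
        assert (
            resolve_polytomies(four_leaf_tree).signature()
            == four_leaf_tree.signature()
        )

    def test_fully_bifurcating_and_leafset_preserved(self, fixture):
        t = resolve_polytomies(fixture.nuclear)
        assert t.leaves == fixture.nuclear.leaves
        for node in t.postorder():
            assert node.is_leaf or len(node.children) == 2


class TestMonophyly:
    def test_examples(self):
        t = parse_newick("((A,B),C);")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_unknown_taxa_error(self):
        with pytest.raises(ValidationError):
            is_monophyletic(parse_newick("((A,B),C);"), {"A", "Z"})

    @pytest.mark.parametrize("seed", range(5))
    def test_every_clade_is_monophyletic(self, seed):
        t = sim_tree(10, seed)
        for _node, clade in t.clades(include_leaves=False):
            assert is_monophyletic(t, clade)


class TestSplitObject:
    def test_complement_is_same_object(self):
        u = frozenset("ABCDE")
        s1 = Split.from_clade(frozenset("AB"), u)
        s2 = Split.from_clade(frozenset("CDE"), u)
        assert s1 == s2 and hash(s1) == hash(s2)

    def test_degenerate_sides_rejected(self):
        u = frozenset("ABC")
        with pytest.raises(ValidationError):
            Split.from_clade(frozenset(), u)
        with pytest.raises(ValidationError):
            Split.from_clade(u, u)
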