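"""Unrooted-tree container, Newick I/O and RF distance semantics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylobench import (
    Bipartition,
    NewickError,
    TreeValidationError,
    bipartitions,
    max_rf,
    parse_newick,
    random_binary_tree,
    relative_rf,
    restrict_to_leaves,
    rf_distance,
    rf_to_reference,
    write_newick,
    zero_one_distance,
)


def split(side_a, side_b):
    return Bipartition(frozenset(side_a), frozenset(side_b))


class TestParseNewick:
    @pytest.mark.parametrize(
        "text, leaves, splits",
        [
            ("((A,B),(C,D));", {"A", "B", "C", "D"}, {("AB", "CD")}),
            ("((A:0.1,B:0.1):0.1,(C:0.5,D:0.5):0.1);", {"A", "B", "C", "D"},
             {("AB", "CD")}),
            ("((A,B),(C,D),E);", {"A", "B", "C", "D", "E"},
             {("AB", "CDE"), ("CD", "ABE")}),
            ("(A,B,C);", {"A", "B", "C"}, set()),
            ("(A,B,C,D,E);", {"A", "B", "C", "D", "E"}, set()),  # star
        ],
    )
    def test_topology(self, text, leaves, splits):
        tree = parse_newick(text)
        assert tree.leaves == leaves
        expected = {split(a, b) for a, b in splits}
        assert bipartitions(tree) == expected

    def test_rooted_and_unrooted_writings_agree(self):
        rooted = parse_newick("((A,B),(C,D));")
        unrooted = parse_newick("(A,B,(C,D));")
        assert rf_distance(rooted, unrooted) == 0

    def test_branch_lengths_kept_and_summed_over_root(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.5,D:0.5):0.2);")
        # the two root-adjacent edges merge into one internal edge 0.1+0.2
        assert tree.leaf_path_length("A", "C") == pytest.approx(0.9)
        assert tree.has_branch_lengths()

    def test_internal_labels_and_support_ignored(self):
        t1 = parse_newick("((A,B)0.95,(C,D)inner);")
        t2 = parse_newick("((A,B),(C,D));")
        assert rf_distance(t1, t2) == 0

    def test_labels_verbatim_no_underscore_interpretation(self):
        tree = parse_newick("((A_x,B),(C,D));")
        assert "A_x" in tree.leaves

    @pytest.mark.parametrize("bad", ["((A,B),(C,D))", "((A,B),C,;", "(A,,B);"])
    def test_malformed_raises_with_offset(self, bad):
        with pytest.raises(NewickError) as err:
            parse_newick(bad)
        assert err.value.offset >= 0

    def test_duplicate_leaf_label_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("((A,B),(A,C));")


class TestWriteNewick:
    def test_quartet_round_trip(self):
        tree = parse_newick("((A,C),(B,D));")
        assert rf_distance(parse_newick(write_newick(tree)), tree) == 0

    def test_three_leaf_star(self):
        tree = parse_newick("(A,B,C);")
        again = parse_newick(write_newick(tree))
        assert again.leaves == {"A", "B", "C"}
        assert bipartitions(again) == frozenset()

    @given(st.integers(4, 25), st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_round_trip_rf_zero(self, n, seed):
        tree = random_binary_tree(n, seed)
        assert rf_distance(parse_newick(write_newick(tree)), tree) == 0


class TestBipartitions:
    def test_quartet(self):
        assert bipartitions(parse_newick("((A,C),(B,D));")) == {
            split("AC", "BD")
        }

    def test_binary_tree_has_n_minus_3_splits(self):
        tree = parse_newick("(((A,B),C),((D,E),F));")
        assert len(bipartitions(tree)) == 3

    def test_canonical_orientation_equality(self):
        assert split("AB", "CD") == split("CD", "AB")
        assert len({split("AB", "CD"), split("DC", "BA")}) == 1


class TestRestrict:
    def test_prune_and_suppress(self):
        tree = parse_newick("(((A,B),C),(D,E));")
        out = restrict_to_leaves(tree, {"A", "B", "C", "D"})
        assert bipartitions(out) == {split("AB", "CD")}

    def test_full_leaf_set_is_identity(self):
        tree = parse_newick("(((A,B),C),(D,E));")
        assert rf_distance(restrict_to_leaves(tree, tree.leaves), tree) == 0

    def test_below_quartet_size_gives_star(self):
        tree = parse_newick("(((A,C),B),D);")
        out = restrict_to_leaves(tree, {"A", "B", "C"})
        assert bipartitions(out) == frozenset()

    def test_unknown_label_rejected(self):
        with pytest.raises(TreeValidationError, match="unknown"):
            restrict_to_leaves(parse_newick("((A,B),(C,D));"), {"A", "Z"})

    def test_branch_lengths_summed_through_suppressed_nodes(self):
        tree = parse_newick("(((A:1,B:1):2,C:1):3,(D:1,E:1):4);")
        out = restrict_to_leaves(tree, {"A", "C", "D", "E"})
        # B pruned: A's path to C keeps the 2-length edge via the collapsed node
        assert out.leaf_path_length("A", "C") == pytest.approx(1 + 2 + 1)

    @given(st.integers(6, 18), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_splits_commute_with_restriction(self, n, seed):
        tree = random_binary_tree(n, seed)
        leaves = sorted(tree.leaves)
        keep = set(leaves[: n // 2 + 2])
        out = restrict_to_leaves(tree, keep)
        expected = {
            r for b in bipartitions(tree) if (r := b.restrict(keep)) is not None
        }
        assert bipartitions(out) == expected


class TestRFDistance:
    def test_wrong_quartet_costs_one(self):
        t1 = parse_newick("((A,C),(B,D));")
        t2 = parse_newick("((A,B),(C,D));")
        assert rf_distance(t1, t2) == 1

    def test_identical_trees_zero(self):
        tree = random_binary_tree(10, seed=1)
        assert rf_distance(tree, tree.copy()) == 0

    def test_single_swap_on_six_leaves(self):
        t1 = parse_newick("((((A,B),C),D),(E,F));")
        t2 = parse_newick("((((A,C),B),D),(E,F));")
        assert rf_distance(t1, t2) == 1

    def test_differing_leaf_sets_rejected(self):
        with pytest.raises(TreeValidationError, match="restrict"):
            rf_distance(parse_newick("((A,B),(C,D));"),
                        parse_newick("((A,B),(C,E));"))

    @given(st.integers(4, 20), st.integers(0, 10**6), st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_symmetric_and_bounded_for_binary_pairs(self, n, s1, s2):
        t1 = random_binary_tree(n, s1)
        t2 = random_binary_tree(n, s2)
        d = rf_distance(t1, t2)
        assert d == rf_distance(t2, t1)
        assert 0 <= d <= max_rf(t1, t2) == n - 3


class TestReferenceDistances:
    def test_star_reference_is_always_matched(self):
        ref = parse_newick("(A,B,C,D,E);")
        tree = parse_newick("(((A,B),C),(D,E));")
        assert rf_to_reference(tree, ref) == 0

    def test_polytomy_resolution_not_penalized(self):
        ref = parse_newick("(A,B,C,(D,E));")
        tree = parse_newick("(((A,B),C),(D,E));")
        assert rf_to_reference(tree, ref) == 0
        assert zero_one_distance(tree, ref) == 0

    def test_missed_reference_split_counts(self):
        ref = parse_newick("(A,B,C,(D,E));")
        tree = parse_newick("(((A,D),C),(B,E));")
        assert rf_to_reference(tree, ref) == 1
        assert zero_one_distance(tree, ref) == 1

    def test_max_rf_of_multifurcating_reference(self):
        ref = parse_newick("(A,B,C,(D,E));")
        tree = parse_newick("(((A,B),C),(D,E));")
        assert max_rf(tree, ref) == 1  # one internal edge, < n-3 = 2

    def test_relative_rf_values(self):
        wrong = parse_newick("((A,C),(B,D));")
        right = parse_newick("((A,B),(C,D));")
        assert relative_rf(wrong, right) == 1.0
        assert relative_rf(right, right.copy()) == 0.0
        t1 = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        t2 = parse_newick("(((A,C),(B,D)),((E,F),(G,H)));")
        assert rf_distance(t1, t2) == 2
        assert relative_rf(t1, t2) == pytest.approx(2 / 5)

    def test_star_reference_relative_flagged_missing(self):
        ref = parse_newick("(A,B,C,D,E);")
        tree = parse_newick("(((A,B),C),(D,E));")
        assert relative_rf(tree, ref) is None
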