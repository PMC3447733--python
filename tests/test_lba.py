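"""Felsenstein-zone quartet simulation and the built-in quartet builders."""

import numpy as np
import pytest

from phylobench import (
    QuartetConfig,
    SaturatedDistanceError,
    SequenceGroup,
    SequenceRecord,
    distance_quartet,
    felsenstein_quartet,
    jc_distance,
    kmer_quartet,
    lba_study,
    parse_newick,
    parsimony_quartet,
    quartet_topologies,
    rf_distance,
    simulate_alignment,
)

TRUE = parse_newick("((A,C),(B,D));")


def dna_group(seqs, og="q"):
    return SequenceGroup(
        og, tuple(SequenceRecord(sp, s, "dna") for sp, s in seqs.items())
    )


class TestFelsensteinQuartet:
    def test_branch_length_placement(self):
        tree = felsenstein_quartet(0.1, 5)
        assert tree.leaf_path_length("A", "B") == pytest.approx(0.3)
        assert tree.leaf_path_length("C", "D") == pytest.approx(1.1)
        assert tree.leaf_path_length("A", "C") == pytest.approx(0.6)

    def test_f_one_makes_all_branches_equal(self):
        tree = felsenstein_quartet(0.2, 1)
        assert tree.leaf_path_length("A", "B") == pytest.approx(0.6)
        assert tree.leaf_path_length("C", "D") == pytest.approx(0.6)

    def test_topology_groups_ac_and_bd(self):
        assert rf_distance(felsenstein_quartet(0.05, 15), TRUE) == 0

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            felsenstein_quartet(0.0, 5)


class TestSimulateAlignment:
    def test_zero_lengths_give_identical_sequences(self):
        tree = parse_newick("((A:0,C:0):0,B:0,D:0);")
        group = simulate_alignment(tree, 50, seed=3)
        seqs = {r.sequence for r in group.records}
        assert len(seqs) == 1

    def test_same_seed_is_byte_identical(self):
        tree = felsenstein_quartet(0.1, 5)
        g1 = simulate_alignment(tree, 200, seed=9)
        g2 = simulate_alignment(tree, 200, seed=9)
        assert [r.sequence for r in g1.records] == [r.sequence for r in g2.records]

    @pytest.mark.parametrize("d", [0.05, 0.5, 1.5])
    def test_jc_mismatch_matches_closed_form(self, d):
        length = 100_000
        tree = parse_newick(f"(A:0.0,B:{d});")
        group = simulate_alignment(tree, length, seed=11)
        s = {r.species: r.sequence for r in group.records}
        p_obs = sum(a != b for a, b in zip(s["A"], s["B"])) / length
        p_exp = 0.75 * (1 - np.exp(-4 * d / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / length)
        assert abs(p_obs - p_exp) < 3 * se

    def test_k2p_transition_bias(self):
        # with kappa >> 1 transitions dominate observed changes
        tree = parse_newick("(A:0.0,B:0.4);")
        group = simulate_alignment(tree, 50_000, model="K2P", kappa=10.0, seed=5)
        s = {r.species: r.sequence for r in group.records}
        purines, pyrimidines = set("AG"), set("CT")
        ts = tv = 0
        for a, b in zip(s["A"], s["B"]):
            if a == b:
                continue
            same_class = (a in purines) == (b in purines)
            ts += same_class
            tv += not same_class
        assert ts > 3 * tv

    def test_missing_branch_length_rejected(self):
        with pytest.raises(Exception, match="length"):
            simulate_alignment(parse_newick("((A,C),(B,D));"), 100, seed=0)


class TestJCDistance:
    def test_identical_sequences(self):
        assert jc_distance("ACGT" * 5, "ACGT" * 5) == 0.0

    def test_closed_form_value(self):
        s1 = "A" * 100
        s2 = "C" * 15 + "A" * 85  # p = 0.15
        assert jc_distance(s1, s2) == pytest.approx(-0.75 * np.log(0.8))
        assert jc_distance(s1, s2) == pytest.approx(0.1673577, abs=1e-6)

    def test_saturation_flag(self):
        s1 = "A" * 100
        s2 = "C" * 75 + "A" * 25  # p = 0.75: formula domain edge
        assert jc_distance(s1, s2) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jc_distance("ACGT", "ACG")


class TestParsimonyQuartet:
    def test_hand_counted_fitch_scores(self):
        # sites (A,B,C,D): (A,A,T,T) x2 and (A,T,A,T) x1 -> scores 4/5/6
        group = dna_group({"A": "AAA", "B": "AAT", "C": "TTA", "D": "TTT"})
        tree, tied = parsimony_quartet(group)
        assert tied == 1
        assert rf_distance(tree, parse_newick("((A,B),(C,D));")) == 0

    def test_single_informative_site(self):
        group = dna_group({"A": "A", "B": "A", "C": "T", "D": "T"})
        tree, tied = parsimony_quartet(group)
        assert rf_distance(tree, parse_newick("((A,B),(C,D));")) == 0

    def test_identical_sequences_three_way_tie(self):
        group = dna_group({k: "ACGTACGT" for k in "ABCD"})
        _, tied = parsimony_quartet(group, rng=np.random.default_rng(0))
        assert tied == 3

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError, match="4 sequences"):
            parsimony_quartet(dna_group({"A": "AC", "B": "AC", "C": "AC"}))


class TestDistanceQuartet:
    def test_four_point_hand_example(self):
        labels = ["A", "B", "C", "D"]
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.2  # A-B
        d[2, 3] = d[3, 2] = 0.2  # C-D
        tree, tied = distance_quartet(d, labels)
        assert tied == 1
        assert rf_distance(tree, parse_newick("((A,B),(C,D));")) == 0

    def test_equidistant_three_way_tie(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0.0)
        _, tied = distance_quartet(d, list("ABCD"), rng=np.random.default_rng(1))
        assert tied == 3

    def test_additive_path_lengths_recover_topology(self):
        quartet = felsenstein_quartet(0.1, 5)
        labels = sorted(quartet.leaves)
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                d[i, j] = d[j, i] = quartet.leaf_path_length(labels[i], labels[j])
        tree, _ = distance_quartet(d, labels)
        assert rf_distance(tree, TRUE) == 0

    def test_saturated_entries_rejected(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0.0)
        d[0, 3] = d[3, 0] = np.nan
        with pytest.raises(SaturatedDistanceError):
            distance_quartet(d, list("ABCD"))


class TestKmerQuartet:
    def test_duplicated_sequences_group_together(self):
        a = "ACGTACGTACGTAAAAACGT"
        b = "GGTTGGTTGGTTGGTTGGCC"
        group = dna_group({"A": a, "B": a, "C": b, "D": b})
        tree, _ = kmer_quartet(group, k=2)
        assert rf_distance(tree, parse_newick("((A,B),(C,D));")) == 0

    def test_identical_sequences_tie(self):
        group = dna_group({k: "ACGTACGTAC" for k in "ABCD"})
        _, tied = kmer_quartet(group, k=3, rng=np.random.default_rng(2))
        assert tied == 3

    def test_too_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            kmer_quartet(dna_group({k: "AC" for k in "ABCD"}), k=4)


class TestQuartetTopologies:
    def test_three_topologies_mutually_distance_one(self):
        tops = quartet_topologies(["A", "B", "C", "D"])
        assert len(tops) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                assert rf_distance(tops[i], tops[j]) == 1


class TestLbaStudy:
    @pytest.fixture(scope="class")
    def small_study(self):
        return lba_study(
            QuartetConfig(n_per_f=6, seq_length=500, seed=5),
            methods=("parsimony", "jc_distance"),
        )

    def test_reproducible_from_seed(self, small_study):
        again = lba_study(
            QuartetConfig(n_per_f=6, seq_length=500, seed=5),
            methods=("parsimony", "jc_distance"),
        )
        assert again.summary.equals(small_study.summary)
        assert again.log.equals(small_study.log)

    def test_parsimony_attracted_distance_corrected(self, small_study):
        s = small_study.summary.set_index("method")
        assert s.loc["parsimony", "taxon"] > s.loc["jc_distance", "taxon"]

    def test_log_covers_grid(self, small_study):
        log = small_study.log
        assert set(log["f"]) == {5.0, 7.5, 10.0, 12.5, 15.0}
        assert log["replicate"].nunique() == 30

    def test_parsimony_inconsistent_deep_in_zone(self):
        # long sequences, strong zone: parsimony locks onto the wrong tree,
        # JC-corrected distances keep the true one
        res = lba_study(
            QuartetConfig(
                f_grid=(10.0,),
                alpha_range=(0.05, 0.0500001),
                seq_length=5000,
                n_per_f=10,
                seed=2,
            ),
            methods=("parsimony", "jc_distance"),
        )
        s = res.summary.set_index("method")
        assert s.loc["parsimony", "taxon"] == 1.0
        assert s.loc["jc_distance", "taxon"] == 0.0
        # systematic failure is consistent: Intra stays low for parsimony
        assert s.loc["parsimony", "intra"] == 0.0

    def test_always_wrong_and_uniform_builders(self):
        # oracle check of the Taxon/Intra bookkeeping on synthetic choices
        from phylobench.lba import _intra_from_choices

        always_same = [2] * 60
        assert _intra_from_choices(always_same) == 0.0
        rng = np.random.default_rng(0)
        uniform = list(rng.integers(0, 3, size=3000))
        assert _intra_from_choices(uniform) == pytest.approx(2 / 3, abs=0.03)

    def test_unknown_builder_rejected(self):
        with pytest.raises(ValueError, match="unknown quartet builder"):
            lba_study(QuartetConfig(n_per_f=1), methods=("magic",))
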