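import itertools

import numpy as np
import pytest

from socmir import (
    BinaryCharacter,
    SpeciesTree,
    TreeError,
    count_independent_gains,
    dollo_reconstruct,
    fitch_min_changes,
    parse_newick,
)
from socmir.phylo import ROOT_STEM

from tests._oracles import enumerate_reconstructions, enumerate_weighted_min_gains


def char(tree, bits):
    leaves = tree.leaf_order()
    return BinaryCharacter("x", dict(zip(leaves, bits)))


class TestParseNewick:
    def test_basic_rooted_tree(self):
        t = parse_newick("((A,B),C);")
        assert t.leaf_order() == ["A", "B", "C"]
        assert len(t.root.children) == 2

    def test_polytomy_preserved(self):
        t = parse_newick("(A,B,C);")
        assert len(t.root.children) == 3

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeError, match="[Dd]uplicate"):
            parse_newick("((A,B),(A,C));")

    def test_malformed_string_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B),C")

    def test_branch_lengths_round_trip(self):
        t = parse_newick("((A:0.5,B:1):2,C:0.25);")
        assert t.to_newick() == "((A:0.5,B:1):2,C:0.25);"

    def test_clade_handles_resolve_by_leaf_set(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        t.bind_clade("inner", ["D", "E", "C"])
        assert t.clade_leaves("inner") == {"C", "D", "E"}
        with pytest.raises(TreeError):
            t.clade_leaves("unbound")


class TestFitch:
    def test_constant_character_costs_nothing(self, eight_leaf_tree):
        rec = fitch_min_changes(eight_leaf_tree, char(eight_leaf_tree, [1] * 8))
        assert rec.total_cost == 0 and rec.events == []

    def test_single_presence_costs_one_terminal_gain(self, eight_leaf_tree):
        rec = fitch_min_changes(
            eight_leaf_tree, char(eight_leaf_tree, [0, 0, 1, 0, 0, 0, 0, 0])
        )
        assert rec.total_cost == 1
        assert rec.events == [("C", "gain")]

    def test_missing_leaf_state_rejected(self, eight_leaf_tree):
        with pytest.raises(TreeError):
            fitch_min_changes(
                eight_leaf_tree, BinaryCharacter("x", {"A": 1})
            )

    def test_relabeling_symmetry(self, eight_leaf_tree, rng):
        for _ in range(50):
            bits = rng.integers(0, 2, size=8)
            a = fitch_min_changes(eight_leaf_tree, char(eight_leaf_tree, bits))
            b = fitch_min_changes(
                eight_leaf_tree, char(eight_leaf_tree, 1 - bits)
            )
            assert a.total_cost == b.total_cost

    def test_event_state_consistency(self, eight_leaf_tree, rng):
        tree = eight_leaf_tree
        for _ in range(30):
            rec = fitch_min_changes(
                tree, char(tree, rng.integers(0, 2, size=8))
            )
            by_branch = dict(rec.events)
            for parent, child in tree.edges():
                a = rec.node_states[parent.node_id]
                b = rec.node_states[child.node_id]
                if a != b:
                    assert by_branch[child.node_id] == (
                        "gain" if b == 1 else "loss"
                    )
                else:
                    assert child.node_id not in by_branch
            assert rec.total_cost == rec.n_gains + rec.n_losses


class TestDollo:
    def test_single_present_leaf_gains_on_terminal_branch(self, eight_leaf_tree):
        rec = dollo_reconstruct(
            eight_leaf_tree, char(eight_leaf_tree, [0, 0, 0, 0, 0, 1, 0, 0])
        )
        assert rec.events == [("F", "gain")]
        assert rec.total_cost == 1

    def test_all_present_gains_on_root_stem(self, eight_leaf_tree):
        rec = dollo_reconstruct(eight_leaf_tree, char(eight_leaf_tree, [1] * 8))
        assert rec.events == [(ROOT_STEM, "gain")]
        assert rec.n_losses == 0

    def test_all_absent_rejected(self, eight_leaf_tree):
        with pytest.raises(TreeError, match="all-absent"):
            dollo_reconstruct(eight_leaf_tree, char(eight_leaf_tree, [0] * 8))

    def test_tip_states_preserved(self, eight_leaf_tree, rng):
        bits = [1, 0, 1, 0, 0, 1, 0, 0]
        rec = dollo_reconstruct(eight_leaf_tree, char(eight_leaf_tree, bits))
        for leaf, s in zip(eight_leaf_tree.leaf_order(), bits):
            assert rec.node_states[leaf] == s


class TestIndependentGains:
    def test_single_present_leaf_is_one_gain(self, eight_leaf_tree):
        c = char(eight_leaf_tree, [1, 0, 0, 0, 0, 0, 0, 0])
        assert count_independent_gains(eight_leaf_tree, c) == 1

    def test_all_present_counts_one_root_stem_gain(self, eight_leaf_tree):
        c = char(eight_leaf_tree, [1] * 8)
        assert count_independent_gains(eight_leaf_tree, c) == 1

    def test_non_positive_costs_rejected(self, eight_leaf_tree):
        c = char(eight_leaf_tree, [1] * 8)
        with pytest.raises(TreeError):
            count_independent_gains(eight_leaf_tree, c, gain_cost=0)

    def test_disjoint_clades_give_two_gains(self):
        t = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        c = BinaryCharacter(
            "x", {l: 1 if l in ("A", "H") else 0 for l in t.leaf_order()}
        )
        assert count_independent_gains(t, c) == 2


class TestAgainstExhaustiveEnumeration:
    """DP results equal brute force over all ancestral assignments."""

    def test_all_characters_on_fixed_tree(self, eight_leaf_tree):
        tree = eight_leaf_tree
        for bits in itertools.product((0, 1), repeat=8):
            c = char(tree, bits)
            fitch_o, gains_o, dollo_o = enumerate_reconstructions(
                tree, c.tip_states
            )
            assert fitch_min_changes(tree, c).total_cost == fitch_o
            assert count_independent_gains(tree, c) == gains_o
            if any(bits):
                assert dollo_reconstruct(tree, c).n_losses == dollo_o

    def test_weighted_gain_counts_match_enumeration(self, eight_leaf_tree, rng):
        tree = eight_leaf_tree
        for gain_cost, loss_cost in ((2.0, 1.0), (1.0, 2.0), (0.5, 1.5)):
            for _ in range(40):
                bits = rng.integers(0, 2, size=8)
                c = char(tree, bits)
                assert count_independent_gains(
                    tree, c, gain_cost, loss_cost
                ) == enumerate_weighted_min_gains(
                    tree, c.tip_states, gain_cost, loss_cost
                )

    def test_polytomy_trees_match_enumeration(self, rng):
        from tests._oracles import random_topology

        for _ in range(20):
            n = int(rng.integers(4, 8))
            tree = parse_newick(random_topology(rng, n))
            for _ in range(20):
                bits = rng.integers(0, 2, size=n)
                c = char(tree, bits)
                fitch_o, gains_o, dollo_o = enumerate_reconstructions(
                    tree, c.tip_states
                )
                assert fitch_min_changes(tree, c).total_cost == fitch_o
                assert count_independent_gains(tree, c) == gains_o
                if any(bits):
                    assert dollo_reconstruct(tree, c).n_losses == dollo_o


def test_dollo_never_beats_fitch(eight_leaf_tree, rng):
    """Dollo restricts the solution space, so its cost is >= Fitch's."""
    tree = eight_leaf_tree
    for _ in range(500):
        bits = rng.integers(0, 2, size=8)
        if not bits.any():
            continue
        c = char(tree, bits)
        assert (
            dollo_reconstruct(tree, c).total_cost
            >= fitch_min_changes(tree, c).total_cost
        )
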