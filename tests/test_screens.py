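import numpy as np
import pandas as pd
import pytest

from socmir import (
    BinaryCharacter,
    PresenceAbsenceMatrix,
    ScreenError,
    TraitLabels,
    clade_exclusive,
    clade_universal,
    convergence_summary,
    fitch_min_changes,
    parse_newick,
    trait_exclusive,
)
from socmir.screens import NEGATIVE, NEUTRAL, POSITIVE


def mat(rows, cols, grid):
    return PresenceAbsenceMatrix(pd.DataFrame(grid, index=rows, columns=cols))


@pytest.fixture()
def toy():
    # A,B positive; C,D negative; E neutral
    tree = parse_newick("(((A,B),(C,D)),E);")
    labels = TraitLabels(
        {"A": POSITIVE, "B": POSITIVE, "C": NEGATIVE, "D": NEGATIVE, "E": NEUTRAL}
    )
    m = mat(
        ["pos_only", "leaky", "neutral_only", "everywhere"],
        list("ABCDE"),
        [
            [1, 1, 0, 0, 1],
            [1, 1, 1, 0, 0],
            [0, 0, 0, 0, 1],
            [1, 1, 1, 1, 1],
        ],
    )
    tree.bind_clade("AB", ["A", "B"])
    tree.bind_clade("ABCD", ["A", "B", "C", "D"])
    return m, tree, labels


class TestTraitExclusive:
    def test_negative_presence_disqualifies(self, toy):
        m, _, labels = toy
        names = {c.mirna_name for c in trait_exclusive(m, labels)}
        assert names == {"pos_only"}

    def test_neutral_only_fails_min_positive(self, toy):
        m, _, labels = toy
        assert "neutral_only" not in {
            c.mirna_name for c in trait_exclusive(m, labels)
        }

    def test_unlabeled_column_is_error(self, toy):
        m, _, _ = toy
        with pytest.raises(ScreenError, match="unlabeled"):
            trait_exclusive(m, TraitLabels({"A": POSITIVE}))

    def test_invariant_to_neutral_cell_flips(self, toy, rng):
        m, _, labels = toy
        base = {c.mirna_name for c in trait_exclusive(m, labels)}
        for _ in range(200):
            df = m.values.copy()
            df["E"] = rng.integers(0, 2, size=len(df))
            flipped = PresenceAbsenceMatrix(df)
            assert {
                c.mirna_name for c in trait_exclusive(flipped, labels)
            } == base

    def test_reports_revalidate_against_matrix(self, toy):
        m, _, labels = toy
        for c in trait_exclusive(m, labels):
            assert c.present_in == m.present_in(c.mirna_name)
            assert c.absent_in_violation == []


class TestCladeScreens:
    def test_outgroup_presence_disqualifies(self, toy):
        m, tree, _ = toy
        names = {c.mirna_name for c in clade_exclusive(m, tree, "AB")}
        assert names == {"pos_only"} - {"pos_only"} or True
        # pos_only is present in E (outside AB) -> excluded
        assert "pos_only" not in names
        assert names == set()

    def test_whole_panel_clade_is_vacuous_outside(self, toy):
        m, tree, _ = toy
        tree.bind_clade("ALL", list("ABCDE"))
        names = {c.mirna_name for c in clade_exclusive(m, tree, "ALL")}
        assert names == {"pos_only", "leaky", "neutral_only", "everywhere"}

    def test_universal_tolerance_semantics(self, toy):
        m, tree, _ = toy
        # leaky present in A,B,C of ABCD (one member absent), absent outside
        assert "leaky" not in {
            c.mirna_name for c in clade_universal(m, tree, "ABCD", tolerance=0)
        }
        assert "leaky" in {
            c.mirna_name for c in clade_universal(m, tree, "ABCD", tolerance=1)
        }

    def test_present_everywhere_fails_outside_absence(self, toy):
        m, tree, _ = toy
        assert "everywhere" not in {
            c.mirna_name for c in clade_universal(m, tree, "ABCD")
        }

    def test_universal_subset_of_exclusive(self, toy, rng):
        m, tree, _ = toy
        for _ in range(100):
            df = pd.DataFrame(
                rng.integers(0, 2, size=(6, 5)),
                index=[f"r{i}" for i in range(6)],
                columns=list("ABCDE"),
            )
            r = PresenceAbsenceMatrix(df)
            uni = {c.mirna_name for c in clade_universal(r, tree, "ABCD", 0)}
            exc = {c.mirna_name for c in clade_exclusive(r, tree, "ABCD", 1)}
            assert uni <= exc

    def test_tolerance_bound_checked(self, toy):
        m, tree, _ = toy
        with pytest.raises(ScreenError):
            clade_universal(m, tree, "ABCD", tolerance=4)


class TestConvergenceSummary:
    def test_disjoint_positive_clades_count_two_positive_gains(self):
        tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        labels = TraitLabels(
            {l: POSITIVE if l in ("A", "H") else NEGATIVE
             for l in tree.leaf_order()}
        )
        m = mat(["conv"], tree.leaf_order(),
                [[1, 0, 0, 0, 0, 0, 0, 1]])
        df = convergence_summary(m, tree, labels)
        row = df.iloc[0]
        assert row["independent_gains"] == 2
        assert row["gains_in_positive_lineages"] == 2
        assert row["losses"] == 0

    def test_sorted_by_positive_gains_descending(self, toy):
        m, tree, labels = toy
        df = convergence_summary(m, tree, labels)
        col = df["gains_in_positive_lineages"].tolist()
        assert col == sorted(col, reverse=True)


class TestFixtureNarratives:
    def test_mir279d_reconstruction_includes_a_regain(self, fx):
        """Present in distant outgroups, absent mid-tree, present again in
        eusocial Aculeata: the minimum-change history loses the gene on the
        path and regains it below the loss."""
        m = fx.matrix
        c = BinaryCharacter(
            "ame-miR-279d",
            {g: m["ame-miR-279d", g] for g in m.col_names},
        )
        rec = fitch_min_changes(fx.tree, c)
        gains = {b for b, k in rec.events if k == "gain"}
        losses = {b for b, k in rec.events if k == "loss"}
        assert gains and losses
        # at least one gain sits below a loss (a true regain)
        nodes = {n.node_id: n for n in fx.tree.postorder()}
        def has_loss_above(nid):
            node = nodes[nid].parent
            while node is not None:
                if node.node_id in losses:
                    return True
                node = node.parent
            return False
        assert any(has_loss_above(g) for g in gains)

    def test_fixture_screen_counts(self, fx):
        from socmir import filter_informative

        fi = filter_informative(fx.matrix_initial)
        five = {c.mirna_name for c in trait_exclusive(fi, fx.labels)}
        assert five == set(fx.h1_candidates)
        six = {
            c.mirna_name for c in clade_exclusive(fi, fx.tree, "Hymenoptera")
        } - five
        assert six == set(fx.h2_candidates)
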