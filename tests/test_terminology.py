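"""DFtree loading, ancestor queries and most-specific filtering."""

from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dfid.stemming import porter_stem
from dfid.terminology import (
    TerminologyError,
    TreeNumber,
    load_terminology,
    stem_concept_name,
)

ORACLE_IDS = list("ABCDEFGH")


def write_tables(tmp_path, concept_rows, tree_rows):
    concepts = tmp_path / "concepts.tsv"
    tree = tmp_path / "tree.tsv"
    concepts.write_text(
        "concept_id\tname\n"
        + "".join(f"{c}\t{n}\n" for c, n in concept_rows)
    )
    tree.write_text(
        "concept_id\ttree_number\n"
        + "".join(f"{c}\t{n}\n" for c, n in tree_rows)
    )
    return concepts, tree


class TestTreeNumber:
    def test_segment_prefix_not_character_prefix(self):
        a = TreeNumber.parse("F4.2")
        b = TreeNumber.parse("F4.23")
        assert not a.is_proper_prefix_of(b)

    def test_proper_prefix(self):
        assert TreeNumber.parse("F4.23").is_proper_prefix_of(
            TreeNumber.parse("F4.23.1"))
        assert not TreeNumber.parse("F4.23").is_proper_prefix_of(
            TreeNumber.parse("F4.23"))

    def test_round_trip(self):
        assert str(TreeNumber.parse("F4.23.1.5")) == "F4.23.1.5"

    @pytest.mark.parametrize("bad", ["", "4.23", "F4..1", ".F4"])
    def test_malformed(self, bad):
        with pytest.raises(TerminologyError):
            TreeNumber.parse(bad)


class TestLoadTerminology:
    def test_tablet_family(self, tmp_path):
        concepts, tree_file = write_tables(
            tmp_path,
            [("C1", "Tablet"), ("C2", "Oral Tablet"), ("C3", "Vaginal Tablet")],
            [("C1", "F4.23"), ("C2", "F4.23.1"), ("C3", "F4.23.2")],
        )
        tree = load_terminology(concepts, tree_file)
        assert len(tree) == 3
        assert tree.is_ancestor("C1", "C2")
        assert tree.is_ancestor("C1", "C3")
        assert not tree.is_ancestor("C2", "C3")

    def test_singleton(self, tmp_path):
        concepts, tree_file = write_tables(
            tmp_path, [("C1", "Solid")], [("C1", "F4")])
        tree = load_terminology(concepts, tree_file)
        assert len(tree) == 1 and not tree.is_ancestor("C1", "C1")

    def test_multi_parent_concept(self, tmp_path):
        concepts, tree_file = write_tables(
            tmp_path,
            [("C1", "Extended Release Enteric Coated Tablet")],
            [("C1", "F4.23.1.4.1"), ("C1", "F4.23.1.5.1")],
        )
        tree = load_terminology(concepts, tree_file)
        concept = tree.get("C1")
        assert len(concept.tree_numbers) == 2
        assert len(tree.index) == 2
        assert all(tree.index[n] == "C1" for n in concept.tree_numbers)

    def test_duplicate_tree_number_rejected(self, tmp_path):
        concepts, tree_file = write_tables(
            tmp_path,
            [("C1", "Tablet"), ("C2", "Capsule")],
            [("C1", "F4.23"), ("C2", "F4.23")],
        )
        with pytest.raises(TerminologyError, match="F4.23"):
            load_terminology(concepts, tree_file)

    def test_unknown_concept_rejected(self, tmp_path):
        concepts, tree_file = write_tables(
            tmp_path, [("C1", "Tablet")],
            [("C1", "F4.23"), ("C9", "F4.24")])
        with pytest.raises(TerminologyError, match="C9"):
            load_terminology(concepts, tree_file)

    def test_empty_concept_table_rejected(self, tmp_path):
        concepts, tree_file = write_tables(tmp_path, [], [])
        with pytest.raises(TerminologyError):
            load_terminology(concepts, tree_file)

    def test_stems_precomputed(self, tmp_path):
        concepts, tree_file = write_tables(
            tmp_path, [("C1", "Oral Solution")], [("C1", "F7.1.1")])
        tree = load_terminology(concepts, tree_file)
        assert tree.get("C1").stems == {"oral", "solut"}


class TestIsAncestor:
    def test_figure_examples(self, mini_tree):
        tablet = mini_tree.id_of("Tablet")
        oral_tablet = mini_tree.id_of("Oral Tablet")
        assert mini_tree.is_ancestor(tablet, oral_tablet)
        assert not mini_tree.is_ancestor(oral_tablet, tablet)

    def test_irreflexive(self, mini_tree):
        solid = mini_tree.id_of("Solid")
        assert not mini_tree.is_ancestor(solid, solid)

    def test_ancestor_through_one_of_several_numbers(self, mini_tree):
        ect = mini_tree.id_of("Enteric Coated Tablet")
        ert = mini_tree.id_of("Extended Release Tablet")
        erect = mini_tree.id_of("Extended Release Enteric Coated Tablet")
        assert mini_tree.is_ancestor(ect, erect)
        assert mini_tree.is_ancestor(ert, erect)

    def test_unknown_id_raises(self, mini_tree):
        with pytest.raises(TerminologyError, match="nope"):
            mini_tree.is_ancestor("nope", mini_tree.id_of("Solid"))


def brute_force_most_specific(tree, candidates):
    return {
        c for c in candidates
        if not any(o != c and tree.is_ancestor(c, o) for o in candidates)
    }


class TestMostSpecific:
    def test_child_beats_parent(self, mini_tree):
        oral = mini_tree.id_of("Oral Tablet")
        ert = mini_tree.id_of("Extended Release Tablet")
        assert mini_tree.most_specific({oral, ert}) == {ert}

    def test_siblings_both_kept(self, mini_tree):
        oral = mini_tree.id_of("Oral Tablet")
        vaginal = mini_tree.id_of("Vaginal Tablet")
        assert mini_tree.most_specific({oral, vaginal}) == {oral, vaginal}

    def test_exhaustive_against_brute_force(self, oracle_tree):
        """Every subset of the 8-node oracle tree is filtered identically
        by the implementation and a pairwise brute-force oracle."""
        for r in range(len(ORACLE_IDS) + 1):
            for subset in combinations(ORACLE_IDS, r):
                assert oracle_tree.most_specific(subset) == (
                    brute_force_most_specific(oracle_tree, set(subset))
                )

    @given(st.sets(st.sampled_from(ORACLE_IDS)))
    def test_idempotent_and_antichain(self, oracle_tree, candidates):
        out = oracle_tree.most_specific(candidates)
        assert oracle_tree.most_specific(out) == out
        assert out <= candidates
        assert not any(
            x != y and oracle_tree.is_ancestor(x, y)
            for x in out for y in out
        )
        if candidates:
            assert out

    @given(st.sampled_from(ORACLE_IDS), st.sampled_from(ORACLE_IDS),
           st.sampled_from(ORACLE_IDS))
    def test_transitivity(self, oracle_tree, a, b, c):
        if oracle_tree.is_ancestor(a, b) and oracle_tree.is_ancestor(b, c):
            assert oracle_tree.is_ancestor(a, c)


class TestStemConceptName:
    def test_oral_solution_two_stems(self):
        stems = stem_concept_name("Oral Solution")
        assert stems == {"oral", "solut"}

    def test_single_word(self):
        assert stem_concept_name("Tablet") == {"tablet"}

    @pytest.mark.parametrize(
        "name", ["Chewable Tablet", "Extended Release Capsule",
                 "Metered Dose Inhaler"])
    def test_matches_word_by_word_stemming(self, name):
        expected = {porter_stem(w) for w in name.lower().split()}
        assert stem_concept_name(name) == expected

    def test_empty_name_rejected(self):
        with pytest.raises(TerminologyError):
            stem_concept_name("   ")
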