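"""Route translation, enrichment, stem-bag matching and the full
identification pipeline, including the published worked examples."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dfid.normalizer import (
    StemBag,
    TranslationRule,
    baseline_identify,
    default_translation_rules,
    enrich_with_routes,
    identify,
    match_dosage_forms,
    to_stem_bag,
    translate_routes,
)
from dfid.stemming import porter_stem
from dfid.text import tokenize
from dfid.title_segmenter import segment_title

from conftest import usage_monograph


def names(tree, ids):
    return {tree.get(c).name for c in ids}


class TestTranslateRoutes:
    def test_by_mouth_to_oral(self, rules):
        out = translate_routes(
            "Moxifloxacin comes as tablet to take by mouth.", rules)
        assert out == "Moxifloxacin comes as tablet to take oral."

    def test_to_the_eyes_variant(self, rules):
        out = translate_routes(
            "an ointment to apply to the eyes.", rules)
        assert "ophthalmic" in out

    def test_no_route_expression_is_identity(self, rules):
        s = "It is a small white tablet."
        assert translate_routes(s, rules) == s

    def test_longest_phrase_wins(self):
        rules = [TranslationRule("into the nose", "nasal"),
                 TranslationRule("the nose", "wrong")]
        out = translate_routes("spray into the nose daily", rules)
        assert out == "spray nasal daily"

    def test_case_insensitive_whole_word(self, rules):
        assert translate_routes("Take By Mouth", rules) == "Take oral"
        # "by mouthful" must not fire the rule
        assert "oral" not in translate_routes("by mouthful", rules)

    def test_single_token_replacement_enforced(self):
        with pytest.raises(ValueError):
            TranslationRule("by mouth", "the oral route")


class TestEnrichWithRoutes:
    def test_propranolol_example(self):
        seg = segment_title("Propranolol Oral")
        out = enrich_with_routes(
            "It also comes as a solution or concentrate.", seg)
        assert out == "It also comes as a solution or concentrate. oral"

    def test_empty_route_is_identity(self):
        seg = segment_title("Acetaminophen")
        s = "It comes as a tablet."
        assert enrich_with_routes(s, seg) == s

    def test_multiple_routes_appended_in_order(self):
        seg = segment_title("Fluticasone Nasal Spray")
        out = enrich_with_routes("Use once daily.", seg)
        assert out.endswith("nasal spray")


class TestToStemBag:
    def test_enriched_sentence_stems(self):
        bag = to_stem_bag("It also comes as a solution or concentrate. oral")
        assert "solut" in bag and "oral" in bag

    def test_empty_sentence(self):
        assert to_stem_bag("").stems == frozenset()

    def test_hyphens_split_tokens(self):
        bag = to_stem_bag("an extended-release tablet")
        assert {"extend", "releas", "tablet"} <= bag.stems

    @given(st.text(alphabet="abcdefgh -.,", max_size=40))
    def test_equals_direct_recomputation(self, sentence):
        bag = to_stem_bag(sentence)
        assert bag.stems == frozenset(
            porter_stem(t) for t in tokenize(sentence))


class TestMatchDosageForms:
    def test_propranolol_bag_matches_oral_solution(self, mini_tree, rules):
        seg = segment_title("Propranolol Oral")
        sentence = enrich_with_routes(
            translate_routes("It also comes as a solution or concentrate.",
                             rules), seg)
        matched = match_dosage_forms(to_stem_bag(sentence), mini_tree)
        assert "Oral Solution" in names(mini_tree, matched)

    def test_moxifloxacin_bag_matches_oral_tablet(self, mini_tree, rules):
        sentence = translate_routes(
            "Moxifloxacin comes as tablet to take by mouth.", rules)
        matched = match_dosage_forms(to_stem_bag(sentence), mini_tree)
        assert "Oral Tablet" in names(mini_tree, matched)

    def test_empty_bag_matches_nothing(self, mini_tree):
        assert match_dosage_forms(StemBag(frozenset()), mini_tree) == set()

    def test_equals_subset_oracle_on_random_bags(self, mini_tree):
        rng = random.Random(20)
        vocabulary = sorted(
            {s for c in mini_tree for s in c.stems}
            | {"take", "daili", "food", "water"})
        for _ in range(300):
            bag = StemBag(frozenset(
                rng.sample(vocabulary, rng.randrange(0, 8))))
            expected = {
                c.concept_id for c in mini_tree if c.stems <= bag.stems}
            assert match_dosage_forms(bag, mini_tree) == expected

    def test_monotone_in_bag_growth(self, mini_tree):
        small = to_stem_bag("an extended release tablet")
        large = to_stem_bag("an extended release tablet taken oral")
        assert (match_dosage_forms(small, mini_tree)
                <= match_dosage_forms(large, mini_tree))


class TestIdentify:
    def test_cyclobenzaprine_cross_match(self, mini_tree, rules):
        """A bag-of-words sentence listing two forms cross-matches the
        modifier of one with the head of the other."""
        m = usage_monograph(
            "cyclobenzaprine", "Cyclobenzaprine",
            "Cyclobenzaprine comes as a tablet and an extended release "
            "capsule to take by mouth.")
        result = identify(m, mini_tree, rules=rules)
        assert names(mini_tree, result.dosage_forms) == {
            "Extended Release Tablet", "Extended Release Capsule"}

    def test_darifenacin_specificity_filter(self, mini_tree, rules):
        m = usage_monograph(
            "darifenacin", "Darifenacin",
            "Darifenacin comes as an extended-release (long-acting) "
            "tablet to take by mouth.")
        result = identify(m, mini_tree, rules=rules)
        assert names(mini_tree, result.dosage_forms) == {
            "Extended Release Tablet"}
        # the more general form was a candidate before filtering
        assert "Oral Tablet" in names(mini_tree, result.candidates)

    def test_no_evidence_sections_yields_empty_result(self, mini_tree,
                                                      rules):
        from dfid.monograph_io import Monograph
        m = Monograph(monograph_id="typhoid-vaccine",
                      title="Typhoid Vaccine",
                      sections={"Why get vaccinated?": "Because."})
        result = identify(m, mini_tree, rules=rules)
        assert result.dosage_forms == set()

    def test_final_set_is_antichain(self, mini_tree, rules):
        m = usage_monograph(
            "x", "Xdrug",
            "Xdrug comes as a tablet, an oral tablet, and an extended "
            "release tablet to take by mouth.")
        result = identify(m, mini_tree, rules=rules)
        forms = result.dosage_forms
        assert not any(
            a != b and mini_tree.is_ancestor(a, b)
            for a in forms for b in forms)

    def test_enrichment_dominance(self, mini_tree, rules):
        m = usage_monograph(
            "propranolol", "Propranolol Oral",
            "It also comes as a solution or concentrate.")
        with_enrich = identify(m, mini_tree, rules=rules)
        without = identify(m, mini_tree, rules=rules, enrich=False)
        assert without.candidates <= with_enrich.candidates
        assert "Oral Solution" in names(mini_tree,
                                        with_enrich.dosage_forms)
        assert "Oral Solution" not in names(mini_tree,
                                            without.dosage_forms)

    def test_evidence_provenance_covers_final_forms(self, mini_tree,
                                                    rules):
        m = usage_monograph(
            "moxifloxacin", "Moxifloxacin",
            "Moxifloxacin comes as tablet to take by mouth.")
        result = identify(m, mini_tree, rules=rules)
        assert {cid for cid, _ in result.evidence} == result.dosage_forms

    def test_deterministic(self, mini_tree, rules):
        m = usage_monograph(
            "x", "Xdrug", "Xdrug comes as an oral solution.")
        a = identify(m, mini_tree, rules=rules)
        b = identify(m, mini_tree, rules=rules)
        assert a.dosage_forms == b.dosage_forms
        assert a.candidates == b.candidates


class TestBaselineIdentify:
    def test_unstemmed_lookup_misses_oral(self, mini_tree):
        m = usage_monograph(
            "x", "Xdrug",
            "Xdrug comes as a tablet to take by mouth every day.")
        result = baseline_identify(m, mini_tree)
        assert names(mini_tree, result.dosage_forms) == {"Tablet"}

    def test_literal_phrase_matches_both_generality_levels(self,
                                                           mini_tree):
        m = usage_monograph(
            "x", "Xdrug", "Xdrug is sold as an oral tablet.")
        result = baseline_identify(m, mini_tree)
        matched = names(mini_tree, result.dosage_forms)
        assert {"Tablet", "Oral Tablet"} <= matched

    def test_empty_section_matches_nothing(self, mini_tree):
        m = usage_monograph("x", "Xdrug", "")
        assert baseline_identify(m, mini_tree).dosage_forms == set()

    def test_no_stemming_in_baseline(self, mini_tree):
        # plural "tablets" does not equal the concept term "tablet"
        m = usage_monograph("x", "Xdrug", "Xdrug comes as tablets.")
        assert baseline_identify(m, mini_tree).dosage_forms == set()
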