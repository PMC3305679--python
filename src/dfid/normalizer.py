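"""Normalizing evidence sentences to standardized dosage-form concepts.

Each evidence sentence goes through four steps:

1. **Route translation** — lay route expressions are rewritten to the
   route tokens used in dosage-form names ("by mouth" -> "oral",
   "to the eyes" -> "ophthalmic").
2. **Title-route enrichment** — the route terms segmented from the title
   are appended to the sentence, so "It also comes as a solution or
   concentrate." under the title "Propranolol Oral" can match
   "Oral Solution".
3. **Stem-bag construction** — the enriched, translated sentence becomes
   a bag of unique word stems.
4. **Dictionary matching** — a dosage-form concept is identified when
   every stem of its name occurs in the bag.

Candidates from all of a monograph's evidence sentences are pooled, then
filtered to the most specific concepts using the terminology hierarchy:
when both "Oral Tablet" and "Extended Release Tablet" match, only the
child survives.  Because matching is bag-of-words, a sentence listing two
forms with shared modifiers can cross-match (e.g. "...a tablet and an
extended release capsule..." also yields "Extended Release Tablet");
this is a known, accepted failure mode of the approach.

A baseline identifier is provided for comparison: a plain unstemmed
whole-word lookup of dosage-form names over the usage section, with no
title segmentation, translation, enrichment or specificity filtering.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .evidence_extractor import EvidenceSentence, extract_evidence
from .monograph_io import Monograph, USAGE_SECTION
from .stemming import Stemmer, porter_stem
from .terminology import DFTree
from .text import tokenize
from .title_segmenter import RouteLexicon, TitleSegmentation, segment_title


@dataclass(frozen=True)
class TranslationRule:
    """Maps a lay route phrase to the route token used in DF names."""

    phrase: str
    replacement: str

    def __post_init__(self) -> None:
        if not self.phrase.strip():
            raise ValueError("empty translation phrase")
        if len(self.replacement.split()) != 1:
            raise ValueError(
                f"replacement must be a single token: {self.replacement!r}"
            )


def default_translation_rules() -> list[TranslationRule]:
    """The shipped rule set (data/translation_rules.tsv)."""
    text = (
        resources.files("dfid").joinpath("data/translation_rules.tsv")
        .read_text(encoding="utf-8")
    )
    return _parse_rules(text.splitlines())


def load_translation_rules(path: str | Path) -> list[TranslationRule]:
    """Load rules from a TSV file with columns phrase, replacement."""
    return _parse_rules(Path(path).read_text(encoding="utf-8").splitlines())


def _parse_rules(lines: Iterable[str]) -> list[TranslationRule]:
    rules = []
    reader = csv.reader(lines, delimiter="\t")
    header = next(reader, None)
    for row in reader:
        if len(row) >= 2 and row[0].strip():
            rules.append(
                TranslationRule(
                    phrase=row[0].strip().lower(),
                    replacement=row[1].strip().lower(),
                )
            )
    return rules


def translate_routes(
    sentence: str, rules: Sequence[TranslationRule]
) -> str:
    """Replace every occurring rule phrase (case-insensitive, whole-word)
    by its replacement token; longer phrases are applied first so "into
    the nose" is not shadowed by a shorter overlapping rule."""
    out = sentence
    for rule in sorted(rules, key=lambda r: -len(r.phrase)):
        pattern = re.compile(
            r"\b" + re.escape(rule.phrase).replace(r"\ ", r"\s+") + r"\b",
            re.IGNORECASE,
        )
        out = pattern.sub(rule.replacement, out)
    return out


def enrich_with_routes(sentence: str, seg: TitleSegmentation) -> str:
    """Append the title's route terms (lowercased) to the sentence;
    unchanged when the title carries no route."""
    if not seg.route_terms:
        return sentence
    return sentence + " " + " ".join(t.lower() for t in seg.route_terms)


@dataclass(frozen=True)
class StemBag:
    """Bag of unique stems for one (translated, enriched) sentence."""

    stems: frozenset[str]
    source_sentence: str = ""

    def __contains__(self, stem: str) -> bool:
        return stem in self.stems


def to_stem_bag(sentence: str, stemmer: Stemmer = porter_stem) -> StemBag:
    """Lowercase, strip punctuation, tokenize, stem, deduplicate."""
    return StemBag(
        stems=frozenset(stemmer(tok) for tok in tokenize(sentence)),
        source_sentence=sentence,
    )


def match_dosage_forms(bag: StemBag, tree: DFTree) -> set[str]:
    """Every concept whose name stems are all present in the bag."""
    return {
        c.concept_id for c in tree if c.stems and c.stems <= bag.stems
    }


@dataclass
class IdentificationResult:
    """Identified dosage forms for one monograph.

    ``dosage_forms`` is the final most-specific set (an antichain in the
    hierarchy); ``candidates`` is the pooled pre-filter set, kept for
    error analysis; ``evidence`` maps each identified concept to the
    sentences that produced it.
    """

    monograph_id: str
    dosage_forms: set[str] = field(default_factory=set)
    candidates: set[str] = field(default_factory=set)
    evidence: list[tuple[str, EvidenceSentence]] = field(default_factory=list)


def identify(
    m: Monograph,
    tree: DFTree,
    lexicon: RouteLexicon | None = None,
    rules: Sequence[TranslationRule] | None = None,
    stemmer: Stemmer = porter_stem,
    *,
    enrich: bool = True,
) -> IdentificationResult:
    """Run the full identification pipeline on one monograph.

    segment title -> extract evidence sentences -> per sentence:
    translate routes, append title routes, build stem bag, match
    concepts -> pool candidates over sentences -> keep most specific.

    *enrich* exists for ablation studies; the method proper always
    enriches.  A monograph without evidence sections yields an empty
    result, never an error.
    """
    if rules is None:
        rules = default_translation_rules()
    seg = segment_title(m.title, lexicon)
    sentences = extract_evidence(m, seg)

    candidates: set[str] = set()
    provenance: list[tuple[str, EvidenceSentence]] = []
    for ev in sentences:
        processed = translate_routes(ev.text, rules)
        if enrich:
            processed = enrich_with_routes(processed, seg)
        bag = to_stem_bag(processed, stemmer)
        matched = match_dosage_forms(bag, tree)
        for cid in sorted(matched):
            provenance.append((cid, ev))
        candidates |= matched

    final = tree.most_specific(candidates) if candidates else set()
    return IdentificationResult(
        monograph_id=m.monograph_id,
        dosage_forms=final,
        candidates=candidates,
        evidence=[(cid, ev) for cid, ev in provenance if cid in final],
    )


def baseline_identify(m: Monograph, tree: DFTree) -> IdentificationResult:
    """Baseline: unstemmed whole-word lookup over the usage section.

    A concept is identified when all tokens of its name occur
    (case-insensitively) anywhere in the "How should this medicine be
    used?" section.  No title handling, no translation, no enrichment,
    no specificity filter.
    """
    text = m.get_section(USAGE_SECTION) or ""
    words = set(tokenize(text))
    matched = {
        c.concept_id for c in tree
        if set(tokenize(c.name)) <= words
    }
    return IdentificationResult(
        monograph_id=m.monograph_id,
        dosage_forms=matched,
        candidates=matched,
        evidence=[],
    )
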