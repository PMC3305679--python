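"""Selecting dosage-form evidence sentences with patterns P1-P5.

The usage sections of a monograph mix dosage-form statements with storage
instructions, warnings, and scheduling advice.  Five surface patterns pick
out the sentences likely to name a physical form:

    P1  sentence contains "come as" (or a verb variant: comes/came/coming)
    P2  sentence contains "come in" (same variants)
    P3  the sentence's first token is one of the title's ingredient terms
    P4  the sentence starts with a determiner + "medication(s)"
    P5  the sentence starts with a determiner + "drug(s)"

A sentence is reported with the lowest-numbered pattern that matches
(precedence P1 > P2 > ... > P5); downstream normalization treats all
evidence sentences identically, so precedence only affects provenance.
The "subject" tests P4/P5 are anchored, parser-free checks: determiner
immediately followed by the keyword at the start of the sentence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .monograph_io import Monograph, iter_evidence_sections
from .text import first_token
from .title_segmenter import TitleSegmentation


class PatternId(str, Enum):
    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    P5 = "P5"


@dataclass(frozen=True)
class EvidenceSentence:
    text: str
    pattern: PatternId
    section_name: str
    monograph_id: str


# verb/noun variants allowed by the patterns; exposed so deployments can
# tighten or extend them without touching code
COME_VARIANTS = ("come", "comes", "came", "coming")
MEDICATION_VARIANTS = ("medication", "medications")
DRUG_VARIANTS = ("drug", "drugs")
DETERMINERS = ("the", "this", "these", "your")

_COME_AS = re.compile(
    r"\b(?:%s)\s+as\b" % "|".join(COME_VARIANTS), re.IGNORECASE)
_COME_IN = re.compile(
    r"\b(?:%s)\s+in\b" % "|".join(COME_VARIANTS), re.IGNORECASE)
_MEDICATION_SUBJECT = re.compile(
    r"^\W*(?:%s)\s+(?:%s)\b" % ("|".join(DETERMINERS),
                                "|".join(MEDICATION_VARIANTS)),
    re.IGNORECASE)
_DRUG_SUBJECT = re.compile(
    r"^\W*(?:%s)\s+(?:%s)\b" % ("|".join(DETERMINERS),
                                "|".join(DRUG_VARIANTS)),
    re.IGNORECASE)

# sentence boundary: terminal punctuation, whitespace, then an uppercase
# letter or digit; a stop-list protects common abbreviations
_ABBREVIATIONS = ("e.g.", "i.e.", "etc.", "dr.", "mr.", "mrs.", "ms.",
                  "vs.", "mg.", "ml.", "no.", "st.", "u.s.")
_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9(])")


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence splitting for monograph prose.

    Splits after ``.?!`` followed by whitespace and a capital or digit,
    unless the token ending the candidate sentence is a known
    abbreviation.  The concatenation of the output equals the input
    modulo whitespace.
    """
    if not text or not text.strip():
        return []
    pieces = _BOUNDARY.split(text.strip())
    sentences: list[str] = []
    for piece in pieces:
        piece = piece.strip()
        if not piece:
            continue
        if sentences:
            prev_last = sentences[-1].rsplit(None, 1)[-1].lower()
            if prev_last in _ABBREVIATIONS:
                sentences[-1] = sentences[-1] + " " + piece
                continue
        sentences.append(piece)
    return sentences


def match_pattern(
    sentence: str, ingredient_terms: Sequence[str] = ()
) -> PatternId | None:
    """Lowest-numbered pattern matching *sentence*, or None.

    *ingredient_terms* are the title's ingredient tokens; P3 fires when
    the sentence's first word token equals any of them, case-insensitive.
    """
    if not sentence.strip():
        return None
    if _COME_AS.search(sentence):
        return PatternId.P1
    if _COME_IN.search(sentence):
        return PatternId.P2
    head = first_token(sentence)
    if head is not None and any(
        head == term.lower() for term in ingredient_terms
    ):
        return PatternId.P3
    if _MEDICATION_SUBJECT.match(sentence):
        return PatternId.P4
    if _DRUG_SUBJECT.match(sentence):
        return PatternId.P5
    return None


def extract_evidence(
    m: Monograph, seg: TitleSegmentation
) -> list[EvidenceSentence]:
    """All pattern-matching sentences of the monograph's evidence
    sections, in document order; empty list when no section or no
    sentence matches."""
    out: list[EvidenceSentence] = []
    for section_name, text in iter_evidence_sections(m):
        for sentence in split_sentences(text):
            pattern = match_pattern(sentence, seg.ingredient_terms)
            if pattern is not None:
                out.append(
                    EvidenceSentence(
                        text=sentence,
                        pattern=pattern,
                        section_name=section_name,
                        monograph_id=m.monograph_id,
                    )
                )
    return out
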