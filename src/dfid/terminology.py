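"""Dosage-form terminology: concepts, tree numbers, and the DFtree.

A dosage-form (DF) terminology assigns every concept one or more dotted
*tree numbers* (e.g. ``F4.23.1`` for "Oral Tablet") that encode its place
in a specificity hierarchy: the more segments, the more specific the
concept.  A concept may carry several tree numbers when it has several
parents — e.g. "Extended Release Enteric Coated Tablet" sits under both
"Enteric Coated Tablet" and "Extended Release Tablet".  The ancestor
relation is defined purely by dotted-segment prefixes over tree numbers,
which makes multi-parent membership fall out naturally and requires no
separate parent pointers.

The terminology is loaded from two TSV tables::

    concepts.tsv   concept_id <TAB> name
    tree.tsv       concept_id <TAB> tree_number     (one row per number)

plus, for silver-standard construction, a branded-drug table::

    branded.tsv    branded_drug_name <TAB> brand_name <TAB> dosage_form_concept_id
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .stemming import Stemmer, porter_stem
from .text import tokenize


class TerminologyError(ValueError):
    """Raised for malformed or inconsistent terminology tables."""


@dataclass(frozen=True, order=True)
class TreeNumber:
    """A dotted tree number such as ``F4.23.1.5``.

    Comparison between numbers is by whole dotted segments, never by
    character prefix: ``F4.2`` is NOT an ancestor number of ``F4.23``.
    """

    segments: tuple[str, ...]

    @classmethod
    def parse(cls, dotted: str) -> "TreeNumber":
        dotted = dotted.strip()
        segments = tuple(s for s in dotted.split("."))
        if not segments or any(not s for s in segments):
            raise TerminologyError(f"malformed tree number: {dotted!r}")
        if not segments[0].startswith("F"):
            raise TerminologyError(
                f"tree number must start with an 'F' segment: {dotted!r}"
            )
        return cls(segments)

    def is_proper_prefix_of(self, other: "TreeNumber") -> bool:
        return (
            len(self.segments) < len(other.segments)
            and other.segments[: len(self.segments)] == self.segments
        )

    def __str__(self) -> str:
        return ".".join(self.segments)


@dataclass(frozen=True)
class DosageFormConcept:
    """One dosage-form concept with its tree numbers and name stems."""

    concept_id: str
    name: str
    tree_numbers: tuple[TreeNumber, ...]
    stems: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tree_numbers:
            raise TerminologyError(
                f"concept {self.concept_id!r} has no tree numbers"
            )


def stem_concept_name(name: str, stemmer: Stemmer = porter_stem) -> frozenset[str]:
    """Stems of a dosage-form name: lowercase, tokenize, stem word-by-word,
    deduplicate.  "Oral Solution" yields ``{"oral", "solut"}`` under Porter.
    """
    if not name.strip():
        raise TerminologyError("empty concept name")
    return frozenset(stemmer(tok) for tok in tokenize(name))


@dataclass(frozen=True)
class BrandedDrugRecord:
    """A branded clinical drug linking a brand name to its dosage form.

    Mirrors RxNorm semantic-branded-drug content: e.g. the record for
    "Fluoxetine 4 MG/ML Oral Solution [Prozac]" carries brand name
    "Prozac" and the concept id of "Oral Solution".  dosage_form_id may
    be empty when the terminology has no DF link for the product.
    """

    branded_drug_name: str
    brand_name: str
    dosage_form_id: str


class DFTree:
    """The dosage-form hierarchy with ancestor queries.

    ``is_ancestor(a, b)`` is true iff some tree number of *a* is a proper
    dotted-segment prefix of some tree number of *b*; the relation is a
    strict partial order.  ``most_specific`` filters a candidate set down
    to the antichain of concepts that are not ancestors of any other
    candidate — the shape a final identification result must have.
    """

    def __init__(self, concepts: Iterable[DosageFormConcept]):
        self.concepts: dict[str, DosageFormConcept] = {}
        self.index: dict[TreeNumber, str] = {}
        self._by_name: dict[str, str] = {}
        for concept in concepts:
            if concept.concept_id in self.concepts:
                raise TerminologyError(
                    f"duplicate concept_id {concept.concept_id!r}"
                )
            self.concepts[concept.concept_id] = concept
            self._by_name[concept.name.lower()] = concept.concept_id
            for number in concept.tree_numbers:
                if number in self.index:
                    raise TerminologyError(
                        f"tree number {number} assigned to both "
                        f"{self.index[number]!r} and {concept.concept_id!r}"
                    )
                self.index[number] = concept.concept_id
        if not self.concepts:
            raise TerminologyError("terminology has no concepts")

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[DosageFormConcept]:
        return iter(self.concepts.values())

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def get(self, concept_id: str) -> DosageFormConcept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise TerminologyError(f"unknown concept_id {concept_id!r}") from None

    def id_of(self, name: str) -> str:
        """Concept id for a concept *name* (case-insensitive); convenience
        for tests and worked examples."""
        try:
            return self._by_name[name.lower()]
        except KeyError:
            raise TerminologyError(f"no concept named {name!r}") from None

    def is_ancestor(self, a: str, b: str) -> bool:
        ca, cb = self.get(a), self.get(b)
        if a == b:
            return False
        return any(
            na.is_proper_prefix_of(nb)
            for na in ca.tree_numbers
            for nb in cb.tree_numbers
        )

    def most_specific(self, candidates: Iterable[str]) -> set[str]:
        """Drop every candidate that is an ancestor of another candidate."""
        cand = set(candidates)
        for cid in cand:
            self.get(cid)  # validate early
        return {
            c for c in cand
            if not any(o != c and self.is_ancestor(c, o) for o in cand)
        }


def _read_tsv(path: str | Path, expected_cols: int, label: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise TerminologyError(f"{label} table {path} is empty")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < expected_cols:
                raise TerminologyError(
                    f"{label} table {path}, line {lineno}: expected "
                    f"{expected_cols} columns, got {len(row)}"
                )
            rows.append([c.strip() for c in row[:expected_cols]])
    return rows


def load_terminology(
    concept_table: str | Path,
    tree_table: str | Path,
    stemmer: Stemmer = porter_stem,
) -> DFTree:
    """Load concept and tree tables into a DFTree, precomputing name stems.

    Raises TerminologyError for duplicate tree numbers, tree rows that
    reference an unknown concept, or an empty concept table.
    """
    names: dict[str, str] = {}
    for concept_id, name in _read_tsv(concept_table, 2, "concept"):
        if concept_id in names:
            raise TerminologyError(f"duplicate concept_id {concept_id!r}")
        names[concept_id] = name
    if not names:
        raise TerminologyError(f"concept table {concept_table} has no rows")

    numbers: dict[str, list[TreeNumber]] = {cid: [] for cid in names}
    for concept_id, dotted in _read_tsv(tree_table, 2, "tree"):
        if concept_id not in names:
            raise TerminologyError(
                f"tree number {dotted!r} references unknown concept "
                f"{concept_id!r}"
            )
        numbers[concept_id].append(TreeNumber.parse(dotted))

    concepts = []
    for concept_id, name in names.items():
        if not numbers[concept_id]:
            raise TerminologyError(
                f"concept {concept_id!r} ({name!r}) has no tree number"
            )
        concepts.append(
            DosageFormConcept(
                concept_id=concept_id,
                name=name,
                tree_numbers=tuple(sorted(numbers[concept_id])),
                stems=stem_concept_name(name, stemmer),
            )
        )
    return DFTree(concepts)


def load_branded_drugs(path: str | Path) -> list[BrandedDrugRecord]:
    """Load the branded-drug table (branded_drug_name, brand_name, DF id).

    An empty dosage_form_id column is preserved as "" and represents a
    product with no dosage-form link in the terminology.
    """
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)  # header
        for row in reader:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            padded = (row + ["", "", ""])[:3]
            rows.append(
                BrandedDrugRecord(
                    branded_drug_name=padded[0].strip(),
                    brand_name=padded[1].strip(),
                    dosage_form_id=padded[2].strip(),
                )
            )
    return rows
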