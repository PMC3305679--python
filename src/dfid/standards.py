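"""Reference standards: manually annotated gold sets and brand-derived
silver sets.

The gold standard is a hand-annotated mapping monograph -> dosage-form
set, loaded from a two-column TSV.  The silver standard is derived
automatically: the brand names listed in a monograph are matched against
branded-drug records (each linking a brand to the dosage form of one
marketed product), and the dosage forms of all matched products are
pooled.  E.g. a monograph listing "Librium" inherits both "Injectable
Solution" and "Oral Capsule" from Librium's two products — which is also
why the silver standard is noisier than the gold one: products can carry
forms the monograph text never discusses.

Monographs for which no silver set can be derived are excluded with a
reason: no brand section at all, no brand name matching any record, or
matched brands whose records carry no dosage-form link.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .monograph_io import Monograph
from .terminology import BrandedDrugRecord, DFTree, TerminologyError


class FailureReason(str, Enum):
    NO_BRAND_SECTION = "NO_BRAND_SECTION"
    BRAND_UNMAPPED = "BRAND_UNMAPPED"
    NO_DF_LINK = "NO_DF_LINK"


@dataclass
class ReferenceStandard:
    """Per-monograph reference dosage-form sets (the answer key F).

    ``entries`` maps monograph ids to nonempty concept-id sets;
    ``excluded`` (silver only) records monographs for which no reference
    set could be derived, with the reason.
    """

    kind: str  # "gold" or "silver"
    entries: dict[str, set[str]] = field(default_factory=dict)
    excluded: dict[str, FailureReason] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("gold", "silver"):
            raise ValueError(f"kind must be gold or silver, got {self.kind!r}")


_TRADEMARK_GLYPHS = str.maketrans("", "", "®™")  # (R), (TM)


def _normalize_brand(name: str) -> str:
    return name.translate(_TRADEMARK_GLYPHS).strip().lower()


def build_silver(
    monographs: Iterable[Monograph],
    branded: Sequence[BrandedDrugRecord],
    tree: DFTree,
) -> ReferenceStandard:
    """Derive the silver standard from brand names and branded-drug
    records.

    Brand matching is case-insensitive exact match after stripping
    trademark glyphs; no fuzzy recovery is attempted.  A monograph is
    excluded only when every brand fails — partial mapping still yields
    an entry with the union of the matched products' dosage forms.
    """
    by_brand: dict[str, list[BrandedDrugRecord]] = defaultdict(list)
    for record in branded:
        if record.dosage_form_id and record.dosage_form_id not in tree:
            raise TerminologyError(
                f"branded drug {record.branded_drug_name!r} references "
                f"unknown dosage form {record.dosage_form_id!r}"
            )
        by_brand[_normalize_brand(record.brand_name)].append(record)

    standard = ReferenceStandard(kind="silver")
    for m in monographs:
        if not m.brand_names:
            standard.excluded[m.monograph_id] = FailureReason.NO_BRAND_SECTION
            continue
        matched_records: list[BrandedDrugRecord] = []
        for brand in m.brand_names:
            matched_records.extend(by_brand.get(_normalize_brand(brand), ()))
        if not matched_records:
            standard.excluded[m.monograph_id] = FailureReason.BRAND_UNMAPPED
            continue
        forms = {r.dosage_form_id for r in matched_records if r.dosage_form_id}
        if not forms:
            standard.excluded[m.monograph_id] = FailureReason.NO_DF_LINK
            continue
        standard.entries[m.monograph_id] = forms
    return standard


def load_gold(gold_file: str | Path, tree: DFTree) -> ReferenceStandard:
    """Load a gold standard TSV (monograph_id, concept_id; one row per
    pair).  Rows referencing a concept absent from the terminology raise
    a load error naming the row."""
    standard = ReferenceStandard(kind="gold")
    with open(gold_file, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise TerminologyError(
                    f"{gold_file}, line {lineno}: expected 2 columns"
                )
            monograph_id, concept_id = row[0].strip(), row[1].strip()
            if concept_id not in tree:
                raise TerminologyError(
                    f"{gold_file}, line {lineno}: unknown concept "
                    f"{concept_id!r} for monograph {monograph_id!r}"
                )
            standard.entries.setdefault(monograph_id, set()).add(concept_id)
    return standard


def write_standard(standard: ReferenceStandard, entries_path: str | Path,
                   excluded_path: str | Path | None = None) -> None:
    """Write entries (and, for silver, the exclusion report) as TSV."""
    with open(entries_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["monograph_id", "concept_id"])
        for monograph_id in sorted(standard.entries):
            for concept_id in sorted(standard.entries[monograph_id]):
                writer.writerow([monograph_id, concept_id])
    if excluded_path is not None:
        with open(excluded_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["monograph_id", "reason"])
            for monograph_id in sorted(standard.excluded):
                writer.writerow(
                    [monograph_id, standard.excluded[monograph_id].value]
                )
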