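"""Reading and writing drug-monograph XML.

A monograph is a consumer-level full-text document about one generic drug
(not a specific product): a title plus named sections.  Two sections carry
dosage-form evidence — "How should this medicine be used?" and "About your
treatment" — and the "Brand names" section lists the marketed products the
silver standard is built from.

The on-disk dialect is deliberately minimal::

    <monograph id="acetaminophen">
      <title>Acetaminophen</title>
      <section name="How should this medicine be used?">free text...</section>
      <section name="Brand names"><brand>Tylenol</brand></section>
    </monograph>

Section lookup is tolerant: heading comparison ignores case and
punctuation, and the two attested spellings "How should this medicine be
used?" / "How should this medication be used?" resolve to the same
canonical section.  Inner markup inside a section is flattened to plain
text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from lxml import etree

USAGE_SECTION = "How should this medicine be used?"
TREATMENT_SECTION = "About your treatment"
BRAND_SECTION = "Brand names"

#: The sections scanned for dosage-form evidence sentences, in the order
#: they are consulted.
EVIDENCE_SECTIONS = (USAGE_SECTION, TREATMENT_SECTION)


class MonographError(ValueError):
    """Raised for malformed monograph XML."""


def _canonical_heading(name: str) -> str:
    key = re.sub(r"[^\w\s]", "", name.lower())
    key = re.sub(r"\s+", " ", key).strip()
    # the corpus uses "medicine" and "medication" interchangeably in this
    # heading; fold them together
    key = key.replace("how should this medication be used",
                      "how should this medicine be used")
    return key


_CANON_USAGE = _canonical_heading(USAGE_SECTION)
_CANON_TREATMENT = _canonical_heading(TREATMENT_SECTION)
_CANON_BRAND = _canonical_heading(BRAND_SECTION)


@dataclass
class Monograph:
    """One drug document: title, named sections, brand-name list."""

    monograph_id: str
    title: str
    sections: dict[str, str] = field(default_factory=dict)
    brand_names: list[str] = field(default_factory=list)

    def get_section(self, name: str) -> str | None:
        """Section text by heading, case- and punctuation-insensitive."""
        want = _canonical_heading(name)
        for heading, text in self.sections.items():
            if _canonical_heading(heading) == want:
                return text
        return None


def parse_monograph(source: str | Path, monograph_id: str | None = None) -> Monograph:
    """Parse one monograph XML file.

    *monograph_id* defaults to the file stem.  Raises MonographError for
    unparsable XML or a missing/empty ``<title>``.
    """
    path = Path(source)
    try:
        root = etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MonographError(f"cannot parse monograph {path.name}: {exc}") from exc
    return _monograph_from_element(root, monograph_id or path.stem, path.name)


def parse_monograph_string(xml_text: str, monograph_id: str) -> Monograph:
    """Parse a monograph from an in-memory XML string."""
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise MonographError(f"cannot parse monograph {monograph_id}: {exc}") from exc
    return _monograph_from_element(root, monograph_id, monograph_id)


def _monograph_from_element(root, monograph_id: str, origin: str) -> Monograph:
    if root.tag != "monograph":
        raise MonographError(f"{origin}: root element is <{root.tag}>, "
                             "expected <monograph>")
    if root.get("id"):
        monograph_id = root.get("id")
    title_el = root.find("title")
    if title_el is None or not (title_el.text or "").strip():
        raise MonographError(f"{origin}: missing or empty <title>")
    title = title_el.text.strip()

    sections: dict[str, str] = {}
    brand_names: list[str] = []
    for sec in root.findall("section"):
        name = sec.get("name", "").strip()
        if not name:
            raise MonographError(f"{origin}: <section> without name attribute")
        if _canonical_heading(name) == _CANON_BRAND:
            brand_names = [
                (b.text or "").strip() for b in sec.findall("brand")
                if (b.text or "").strip()
            ]
            sections[name] = " ".join(brand_names)
        else:
            # flatten inner markup to plain text
            text = " ".join("".join(sec.itertext()).split())
            sections[name] = text
    return Monograph(
        monograph_id=monograph_id,
        title=title,
        sections=sections,
        brand_names=brand_names,
    )


def write_monograph(m: Monograph, path: str | Path) -> None:
    """Serialize a Monograph back to the XML dialect (round-trip safe)."""
    root = etree.Element("monograph", id=m.monograph_id)
    etree.SubElement(root, "title").text = m.title
    for name, text in m.sections.items():
        sec = etree.SubElement(root, "section", name=name)
        if _canonical_heading(name) == _CANON_BRAND:
            for brand in m.brand_names:
                etree.SubElement(sec, "brand").text = brand
        else:
            sec.text = text
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True,
                       encoding="UTF-8")
    )


def read_monograph_dir(directory: str | Path) -> list[Monograph]:
    """Parse every ``*.xml`` file in *directory*, sorted by file name."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.xml"))
    return [parse_monograph(p) for p in paths]


def get_evidence_sections(m: Monograph) -> list[str]:
    """Texts of the evidence sections that exist, in document order.

    Monographs without either section (e.g. vaccines) yield an empty
    list, which propagates to an empty identification result downstream.
    """
    return [text for _, text in iter_evidence_sections(m)]


def iter_evidence_sections(m: Monograph) -> list[tuple[str, str]]:
    """(heading, text) pairs of the evidence sections, in document order."""
    wanted = {_CANON_USAGE, _CANON_TREATMENT}
    return [
        (heading, text) for heading, text in m.sections.items()
        if _canonical_heading(heading) in wanted and text.strip()
    ]
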