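"""Synthetic monograph corpora with known ground truth.

Real drug monographs and full terminology releases are licensed and
cannot ship with the package, so every stage is exercised against a
generated stand-in corpus instead: a mini dosage-form tree modelled on
the published hierarchy fragment (Solid > Tablet > Oral Tablet > ... with
a multi-parent "Extended Release Enteric Coated Tablet"), monographs
whose evidence sentences are instantiated from the five extraction
patterns, a branded-drug table consistent with the planted dosage forms,
and gold labels plus a manifest recording exactly what was planted.

Noise knobs:

* ``route_noise`` — probability that a planted sentence expresses the
  route as a lay phrase ("to take by mouth") that must be translated to
  recover the route token, rather than using the token directly.
* ``distractor_rate`` — probability of inserting non-evidence sentences
  (storage/warning prose matching no pattern) around planted sentences.
* ``brand_dropout`` — probability that a monograph omits its "Brand
  names" section, which makes silver-standard construction fail for it.

Planted dosage-form sets are antichains of leaf concepts (1-3 per
monograph, mean about 1.6, close to the 1.55 forms/monograph observed in
hand-annotated corpora of this kind).  The generator combines two forms
into one sentence only when the combined bag of stems introduces no
concept beyond what the separate sentences yield, so that under default
settings the pipeline provably recovers the gold labels exactly; the
bag-of-words cross-match failure mode is exercised by dedicated worked-
example tests instead of being hidden in the corpus.

All outputs are pure functions of the spec (including its seed).
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

from .monograph_io import (
    BRAND_SECTION,
    TREATMENT_SECTION,
    USAGE_SECTION,
    Monograph,
    write_monograph,
)
from .normalizer import (
    default_translation_rules,
    match_dosage_forms,
    to_stem_bag,
    translate_routes,
)
from .terminology import (
    BrandedDrugRecord,
    DFTree,
    DosageFormConcept,
    TreeNumber,
    stem_concept_name,
)

# ---------------------------------------------------------------------------
# mini terminology

#: The fixed hierarchy backbone: (name, tree numbers).  The multi-parent
#: concept carries two numbers, one under Enteric Coated Tablet and one
#: under Extended Release Tablet.
BACKBONE: list[tuple[str, tuple[str, ...]]] = [
    ("Solid", ("F4",)),
    ("Tablet", ("F4.23",)),
    ("Oral Tablet", ("F4.23.1",)),
    ("Vaginal Tablet", ("F4.23.2",)),
    ("Chewable Tablet", ("F4.23.1.2",)),
    ("Enteric Coated Tablet", ("F4.23.1.4",)),
    ("Extended Release Tablet", ("F4.23.1.5",)),
    ("Extended Release Enteric Coated Tablet",
     ("F4.23.1.4.1", "F4.23.1.5.1")),
    ("Capsule", ("F4.24",)),
    ("Oral Capsule", ("F4.24.1",)),
    ("Extended Release Capsule", ("F4.24.1.1",)),
    ("Liquid", ("F7",)),
    ("Solution", ("F7.1",)),
    ("Oral Solution", ("F7.1.1",)),
    ("Injectable Solution", ("F7.1.2",)),
    ("Ophthalmic Solution", ("F7.1.3",)),
]

#: Optional extra leaf concepts, appended in order until n_forms is met.
EXTRA_FORMS: list[tuple[str, tuple[str, ...]]] = [
    ("Otic Solution", ("F7.1.4",)),
    ("Oral Suspension", ("F7.3.1",)),
    ("Nasal Spray", ("F7.2.1",)),
    ("Topical Cream", ("F6.1",)),
    ("Rectal Suppository", ("F4.30.1",)),
    ("Transdermal Patch", ("F5.1",)),
    ("Inhalation Powder", ("F4.40.1",)),
]

#: Leaf concepts a monograph may be assigned, with the sentence phrase
#: used when the route token appears verbatim (direct) and, where a lay
#: paraphrase exists, the phrase that needs route translation (lay).
PLANTABLE: dict[str, tuple[str, str | None]] = {
    "Vaginal Tablet": (
        "a vaginal tablet", "a tablet to insert into the vagina"),
    "Chewable Tablet": ("a chewable tablet", None),
    "Extended Release Enteric Coated Tablet": (
        "an extended release enteric coated tablet", None),
    "Extended Release Capsule": (
        "an extended release capsule",
        "an extended release capsule to take by mouth"),
    "Oral Solution": ("an oral solution", "a solution to take by mouth"),
    "Injectable Solution": ("an injectable solution", None),
    "Ophthalmic Solution": (
        "an ophthalmic solution",
        "a solution (liquid) to apply to the eyes"),
    "Otic Solution": ("an otic solution", "a solution to place into the ear"),
    "Oral Suspension": (
        "an oral suspension", "a suspension to take by mouth"),
    "Nasal Spray": ("a nasal spray", "a spray to use into the nose"),
    "Topical Cream": ("a topical cream", "a cream to apply on the skin"),
    "Rectal Suppository": (
        "a rectal suppository", "a suppository to insert into the rectum"),
    "Transdermal Patch": ("a transdermal patch", None),
    "Inhalation Powder": ("an inhalation powder", None),
}

#: Concepts whose sentences remain unambiguous when the title route
#: "Oral" is appended to every evidence sentence of the monograph; only
#: monographs planted entirely from this set may move the route into the
#: title.  For the oral-named members the sentence then drops the route
#: word, so recovery depends on title-route enrichment.
_ORAL_SAFE = frozenset({
    "Chewable Tablet",
    "Extended Release Enteric Coated Tablet",
    "Extended Release Capsule",
    "Oral Solution",
    "Oral Suspension",
})

_DISTRACTORS = [
    "Store it at room temperature and away from excess heat and moisture.",
    "Follow the directions on your prescription label carefully.",
    "Ask your pharmacist to explain any part you do not understand.",
    "Do not stop taking it without talking to your doctor.",
    "If you miss a dose, skip the missed dose and continue your regular "
    "dosing schedule.",
    "Keep all appointments with your doctor and the laboratory.",
]

_SYLLABLES = ["va", "zo", "ly", "pra", "xel", "tor", "min",
              "dex", "cor", "bal", "ner", "ri", "fen", "lu"]
_ING_SUFFIXES = ["ol", "ine", "ide", "ac", "in", "one"]

_TITLE_ROUTE_P = 0.3    # chance an oral-safe monograph moves its route
_COMBINE_P = 0.3        # chance two forms share one sentence (if safe)
_TREATMENT_SECTION_P = 0.1
_SECOND_BRAND_P = 0.3


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one generated corpus; identical specs give
    byte-identical output."""

    seed: int = 0
    n_monographs: int = 50
    n_forms: int = 16
    route_noise: float = 0.5
    brand_dropout: float = 0.0
    distractor_rate: float = 0.5
    #: P(1), P(2), P(3) planted forms per monograph; mean 1.6
    df_count_weights: tuple[float, float, float] = (0.5, 0.4, 0.1)

    def __post_init__(self) -> None:
        for p in (self.route_noise, self.brand_dropout, self.distractor_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_monographs < 1:
            raise ValueError("n_monographs must be positive")
        if self.n_forms < 4:
            raise ValueError("n_forms must be at least 4")


def generate_terminology(
    spec: FixtureSpec,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Concept and tree rows of the mini terminology.

    The backbone is always emitted in full (n_forms below its size is
    treated as the backbone minimum); extra leaves are appended until
    n_forms concepts exist or the extras run out.
    """
    forms = list(BACKBONE)
    for extra in EXTRA_FORMS:
        if len(forms) >= spec.n_forms:
            break
        forms.append(extra)
    concept_rows = []
    tree_rows = []
    for i, (name, numbers) in enumerate(forms, start=1):
        cid = f"DF{i:02d}"
        concept_rows.append((cid, name))
        for number in numbers:
            tree_rows.append((cid, number))
    return concept_rows, tree_rows


def _build_tree(concept_rows, tree_rows) -> DFTree:
    numbers: dict[str, list[TreeNumber]] = {}
    for cid, dotted in tree_rows:
        numbers.setdefault(cid, []).append(TreeNumber.parse(dotted))
    return DFTree(
        DosageFormConcept(
            concept_id=cid,
            name=name,
            tree_numbers=tuple(numbers[cid]),
            stems=stem_concept_name(name),
        )
        for cid, name in concept_rows
    )


def _coin(rng: random.Random, p: float) -> bool:
    return rng.random() < p


def _coin_word(rng: random.Random, used: set[str], suffixes) -> str:
    while True:
        word = "".join(rng.choice(_SYLLABLES) for _ in range(2))
        word += rng.choice(suffixes)
        if word not in used:
            used.add(word)
            return word.capitalize()


def _sentence_templates(drug: str):
    return [
        ("P1", f"{drug} comes as {{phrase}}."),
        ("P1", f"{drug} comes as {{phrase}}."),
        ("P1", f"It also comes as {{phrase}}."),
        ("P2", f"{drug} comes in {{phrase}}."),
        ("P3", f"{drug} is available as {{phrase}}."),
        ("P4", "The medication is supplied as {phrase}."),
        ("P5", "The drug is given as {phrase}."),
    ]


def _match_phrase(phrase: str, tree: DFTree, title_route: str | None,
                  rules) -> set[str]:
    """Concepts the pipeline would match for one sentence built from
    *phrase*, under the default translation rules and title enrichment."""
    text = translate_routes(phrase, rules)
    if title_route:
        text += " " + title_route
    return match_dosage_forms(to_stem_bag(text), tree)


def generate_corpus(spec: FixtureSpec, out_dir: str | Path | None = None):
    """Generate the full fixture set.

    Returns ``(tree, monographs, branded, gold, manifest)``; when
    *out_dir* is given, additionally writes ``monographs/*.xml``,
    ``terminology/{concepts,tree,branded}.tsv``, ``gold.tsv`` and
    ``manifest.json`` under it.
    """
    rng = random.Random(spec.seed)
    concept_rows, tree_rows = generate_terminology(spec)
    tree = _build_tree(concept_rows, tree_rows)
    rules = default_translation_rules()

    plantable = [
        tree.id_of(name) for name in PLANTABLE
        if name.lower() in {n.lower() for _, n in concept_rows}
    ]
    name_of = {cid: tree.get(cid).name for cid in plantable}

    used_words: set[str] = set()
    monographs: list[Monograph] = []
    branded: list[BrandedDrugRecord] = []
    gold: dict[str, set[str]] = {}
    manifest: dict = {"spec": asdict(spec), "monographs": {}}

    for _ in range(spec.n_monographs):
        ingredient = _coin_word(rng, used_words, _ING_SUFFIXES)
        monograph_id = ingredient.lower()

        # planted antichain of leaf forms
        n_forms = rng.choices((1, 2, 3), weights=spec.df_count_weights)[0]
        planted: list[str] = []
        for _ in range(200):  # rejection sampling; the leaf pool is flat
            cand = rng.sample(plantable, min(n_forms, len(plantable)))
            if not any(
                tree.is_ancestor(a, b)
                for a in cand for b in cand if a != b
            ):
                planted = cand
                break
        if not planted:
            raise RuntimeError("could not sample an antichain of forms")
        planted_names = [name_of[c] for c in planted]

        title_route = (
            "oral"
            if all(n in _ORAL_SAFE for n in planted_names)
            and _coin(rng, _TITLE_ROUTE_P)
            else None
        )
        title = ingredient + (" Oral" if title_route else "")

        # one phrase per planted form
        phrases: list[str] = []
        for cid in planted:
            direct, lay = PLANTABLE[name_of[cid]]
            if title_route:
                name = name_of[cid]
                if name.startswith("Oral "):
                    # route moves to the title; drop it from the phrase
                    phrase = direct.replace("an oral ", "a ").replace(
                        "a oral ", "a ")
                else:
                    phrase = direct
            elif lay is not None and _coin(rng, spec.route_noise):
                phrase = lay
            else:
                phrase = direct
            phrases.append(phrase)

        # optionally merge two phrases into one sentence when the merged
        # bag matches nothing beyond the separate bags
        merged: list[str] = []
        i = 0
        while i < len(phrases):
            if (
                i + 1 < len(phrases)
                and _coin(rng, _COMBINE_P)
            ):
                combo = phrases[i] + " and " + phrases[i + 1]
                separate = (
                    _match_phrase(phrases[i], tree, title_route, rules)
                    | _match_phrase(phrases[i + 1], tree, title_route, rules)
                )
                if _match_phrase(combo, tree, title_route, rules) <= separate:
                    merged.append(combo)
                    i += 2
                    continue
            merged.append(phrases[i])
            i += 1

        sentences: list[tuple[str, str]] = []  # (expected pattern, text)
        templates = _sentence_templates(ingredient)
        for k, phrase in enumerate(merged):
            if k == 0:
                pattern, template = rng.choice(templates[:2])  # lead with P1
            else:
                pattern, template = rng.choice(templates)
            sentences.append((pattern, template.format(phrase=phrase)))

        # distractors around the evidence sentences
        body: list[str] = []
        for _, text in sentences:
            if _coin(rng, spec.distractor_rate):
                body.append(rng.choice(_DISTRACTORS))
            body.append(text)
        if _coin(rng, spec.distractor_rate):
            body.append(rng.choice(_DISTRACTORS))

        section_name = (
            TREATMENT_SECTION
            if _coin(rng, _TREATMENT_SECTION_P)
            else USAGE_SECTION
        )

        # brands and branded-drug records covering the planted forms
        n_brands = 2 if _coin(rng, _SECOND_BRAND_P) else 1
        brands = [_coin_word(rng, used_words, ["xa", "von", "eq"])
                  for _ in range(n_brands)]
        for j, cid in enumerate(planted):
            brand = brands[j % n_brands]
            strength = rng.randrange(1, 50) * 10
            branded.append(
                BrandedDrugRecord(
                    branded_drug_name=(
                        f"{ingredient} {strength} MG {name_of[cid]} [{brand}]"
                    ),
                    brand_name=brand,
                    dosage_form_id=cid,
                )
            )

        has_brand_section = not _coin(rng, spec.brand_dropout)
        sections = {section_name: " ".join(body)}
        monograph = Monograph(
            monograph_id=monograph_id,
            title=title,
            sections=sections,
            brand_names=brands if has_brand_section else [],
        )
        if has_brand_section:
            monograph.sections[BRAND_SECTION] = " ".join(brands)

        monographs.append(monograph)
        gold[monograph_id] = set(planted)
        manifest["monographs"][monograph_id] = {
            "title": title,
            "planted": sorted(planted),
            "planted_names": sorted(name_of[c] for c in planted),
            "sentences": [
                {"pattern": p, "text": t} for p, t in sentences
            ],
            "brands": brands,
            "has_brand_section": has_brand_section,
            "section": section_name,
            "expected": sorted(planted),
        }

    if out_dir is not None:
        _write_corpus(
            Path(out_dir), concept_rows, tree_rows, branded,
            monographs, gold, manifest,
        )
    return tree, monographs, branded, gold, manifest


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def _write_corpus(out_dir, concept_rows, tree_rows, branded,
                  monographs, gold, manifest) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    term_dir = out_dir / "terminology"
    term_dir.mkdir(exist_ok=True)
    mono_dir = out_dir / "monographs"
    mono_dir.mkdir(exist_ok=True)

    _write_tsv(term_dir / "concepts.tsv", ["concept_id", "name"],
               concept_rows)
    _write_tsv(term_dir / "tree.tsv", ["concept_id", "tree_number"],
               tree_rows)
    _write_tsv(
        term_dir / "branded.tsv",
        ["branded_drug_name", "brand_name", "dosage_form_concept_id"],
        [(b.branded_drug_name, b.brand_name, b.dosage_form_id)
         for b in branded],
    )
    _write_tsv(
        out_dir / "gold.tsv", ["monograph_id", "concept_id"],
        [(mid, cid) for mid in sorted(gold) for cid in sorted(gold[mid])],
    )
    for m in monographs:
        write_monograph(m, mono_dir / f"{m.monograph_id}.xml")
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
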