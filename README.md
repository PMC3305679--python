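# dfid — dosage-form identification in drug monographs

`dfid` identifies the **dosage forms** (Oral Tablet, Injectable Solution,
Ophthalmic Solution, ...) that a full-text drug monograph discusses, and
normalizes them to concepts of a standardized dosage-form terminology
organized as a specificity hierarchy of dotted tree numbers (the style of
RxNorm's DF inventory: `F4` Solid → `F4.23` Tablet → `F4.23.1` Oral
Tablet).  It is aimed at people building links between drug information
resources — the same ingredient in different dosage forms is, for most
practical purposes, a different drug.

The method is rule-based and consists of four steps per monograph:

1. **Title segmentation.**  Monograph titles follow an
   *ingredient + optional route* pattern ("Propranolol Oral",
   "Diclofenac Ophthalmic").  The title is split at the leftmost token
   found in a route-marker lexicon into ingredient terms *I* and route
   terms *R*.
2. **Evidence-sentence extraction.**  The sections "How should this
   medicine be used?" and "About your treatment" are split into
   sentences, and five surface patterns select the sentences likely to
   name a physical form: *P1* "…come as…", *P2* "…come in…", *P3* first
   token is an ingredient term, *P4*/*P5* determiner + "medication"/
   "drug" subject.
3. **Route translation and title enrichment.**  Lay route phrases are
   rewritten to terminology route tokens ("by mouth" → "oral", "to the
   eyes" → "ophthalmic"), and the title routes *R* are appended to every
   evidence sentence.
4. **Stem-bag matching and specificity filtering.**  Each processed
   sentence becomes a bag of unique Porter stems; a concept is matched
   when all stems of its name ("Oral Solution" → {oral, solut}) occur in
   the bag.  Candidates pooled over sentences are filtered to the *most
   specific* set *D* using the tree-number hierarchy (if both "Oral
   Tablet" and its child "Extended Release Tablet" match, only the child
   is kept).

Evaluation is per monograph against a reference set *F*:
*P* = |D∩F|/|D|, *R* = |D∩F|/|F|, *F₁* = 2PR/(P+R), macro-averaged over
monographs (mean, SD, median, IQR).  Besides manually annotated gold
labels, the package can derive a **silver standard** automatically: the
brand names listed in a monograph are matched to branded-drug records
and the dosage forms of all matched products are pooled.  A baseline
identifier (plain unstemmed name lookup over the usage section) is
included for comparison.

Because real monograph corpora and terminology releases are licensed,
the package ships a first-class **synthetic corpus generator** with
known ground truth (planted dosage forms, evidence sentences, brands)
and controllable noise — lay-route phrasing, distractor sentences,
missing brand sections.

## Worked example

```python
from dfid import FixtureSpec, Monograph, identify, prf
from dfid.fixtures import generate_terminology, _build_tree
from dfid.normalizer import default_translation_rules

tree = _build_tree(*generate_terminology(FixtureSpec()))
m = Monograph(
    monograph_id="cyclobenzaprine", title="Cyclobenzaprine",
    sections={"How should this medicine be used?":
              "Cyclobenzaprine comes as a tablet and an extended "
              "release capsule to take by mouth."})
result = identify(m, tree, rules=default_translation_rules())
print(sorted(tree.get(c).name for c in result.dosage_forms))
gold = {tree.id_of("Oral Tablet"), tree.id_of("Extended Release Capsule")}
metrics = prf(result.dosage_forms, gold)
print(metrics.precision, metrics.recall, metrics.f_measure)
```

prints

```
['Extended Release Capsule', 'Extended Release Tablet']
0.5 0.5 0.5
```

"by mouth" is translated to "oral", the sentence becomes one stem bag,
and the bag cross-matches the *tablet* token with the *extended release*
modifier of the capsule — so the correct "Extended Release Capsule" is
found together with a spurious "Extended Release Tablet" (and the true
"Oral Tablet" is lost to the specificity filter).  Scored against the
annotated set, precision, recall and F-measure are all exactly 0.5.
This is the characteristic failure mode of bag-of-words matching, and
the package reproduces it faithfully.

## Command line

```
dfid fixtures --seed 7 --n 200 --out corpus/
dfid identify --monographs corpus/monographs \
    --concepts corpus/terminology/concepts.tsv \
    --tree corpus/terminology/tree.tsv --out pred.tsv
dfid silver   --monographs corpus/monographs \
    --branded corpus/terminology/branded.tsv \
    --concepts corpus/terminology/concepts.tsv \
    --tree corpus/terminology/tree.tsv --out silver.tsv
dfid evaluate --pred pred.tsv --standard corpus/gold.tsv \
    --concepts corpus/terminology/concepts.tsv \
    --tree corpus/terminology/tree.tsv --out summary.tsv
```

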