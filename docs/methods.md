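# Methods

## The model

`dfid` treats dosage-form identification as dictionary lookup over a
normalized sentence representation, guarded by hand-written extraction
rules.  The core assumptions are:

* **Monograph structure is stable.**  Titles follow
  *ingredient + optional route*; dosage-form statements live almost
  exclusively in the "How should this medicine be used?" and "About
  your treatment" sections; the "Brand names" section lists marketed
  products.  The method is not expected to transfer to documents
  without this structure.
* **Dosage-form names are short compositional noun phrases.**  A
  concept such as "Extended Release Capsule" is fully characterized by
  the unordered set of its word stems, so subset testing over a stem
  bag is a sound (if over-permissive) matcher.
* **Specificity is encoded positionally.**  Dotted tree numbers define
  the hierarchy: concept *a* is an ancestor of *b* iff some tree number
  of *a* is a proper dotted-*segment* prefix of some number of *b*
  (`F4.2` is not a prefix of `F4.23`).  Multi-parent concepts simply
  carry several numbers; no parent pointers are stored.  The final
  prediction is always an antichain under this order.

The deliberate weakness of the representation — word order and within-
sentence association are discarded — produces a characteristic error:
a sentence listing "a tablet and an extended release capsule" also
matches "Extended Release Tablet".  This is reproduced, documented and
tested, not patched, because positional modelling is explicitly outside
the method.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| Stemmer | Porter (1980) | The standard suffix stripper; consistent with the intended mapping "solution" → "solut". Implemented in `dfid.stemming`; any `str -> str` callable can be substituted, and the baseline uses a lowercase-only identity stemmer. |
| Route-marker lexicon | 10 terms (`data/route_markers.txt`) | The attested title routes (nasal, ophthalmic, otic, oral, rectal, vaginal) plus the equally conventional topical, transdermal, injection, inhalation. Plain-text file, one term per line, replaceable per run. |
| Translation rules | 25 rules (`data/translation_rules.tsv`) | The five canonical lay-route mappings (by mouth → oral, into nose → nasal, into ear → otic, on skin → topical, in eye → ophthalmic) plus surface variants ("to the eyes", "into the ears", ...) and three parenteral phrases. Longest phrase wins; matching is case-insensitive and word-bounded. |
| Pattern variant sets | come/comes/came/coming; medication(s); drug(s); determiners the/this/these/your | Closed-class; exposed as module constants. |
| Pattern precedence | P1 > P2 > P3 > P4 > P5, first match wins | Downstream processing is identical for all patterns, so precedence affects only provenance reporting. |
| Scoring | exact set match; empty prediction ⇒ P = R = F = 0 | Monographs where the method returns nothing (e.g. vaccines without usage sections) count as failures, not skips. A hierarchical-credit mode (ancestor/descendant counts as a match) exists behind a flag and is off by default. |
| Summary statistics | mean, sample SD (n−1), median, IQR (linear-interpolation quartiles, Q3−Q1) | Stated so independent recomputation agrees bit-for-bit. |

## Design choices where the design was open

* **Enrichment is unconditional**: title routes are appended to every
  evidence sentence, not only those lacking a route.  Matching is
  set-based, so duplicates are harmless, and the rule needs no
  within-sentence route detector.
* **Candidates are pooled per monograph** across all evidence sentences
  before the specificity filter, because the target of identification
  is the monograph, not the sentence.
* **Tokenization** lowercases, treats hyphens and slashes as
  separators, and strips other punctuation — "extended-release" must
  match "Extended Release".  The same tokenizer serves concept names,
  sentences and the baseline.
* **The baseline is unstemmed by construction**: it looks up the raw
  name tokens of every concept in the whole usage section, with no
  title handling, translation, enrichment or filtering.  It exists to
  quantify what the rules add.
* **The CLI is flag-driven.**  Every run parameter is a path or scalar
  flag and the effective configuration is hashed into the log, so a
  separate config-file layer would add indirection without
  reproducibility benefit.
* **Brand matching is exact** (case-insensitive, trademark glyphs ®/™
  stripped).  Fuzzy recovery is not attempted; unmatched brands are
  reported as an exclusion reason (`BRAND_UNMAPPED`), alongside
  `NO_BRAND_SECTION` and `NO_DF_LINK`.
* **Degenerate inputs**: a monograph without evidence sections yields
  an empty result, never an error; an empty reference set raises,
  because the standards builder is required to exclude such monographs
  rather than pass them through; duplicate tree numbers are a load
  error, not a tie to resolve.

## The synthetic corpus generator

`dfid.fixtures` generates corpora with known ground truth: a mini
terminology whose backbone mirrors the published hierarchy fragment
(Solid/Tablet/Oral Tablet/Vaginal Tablet, the extended-release and
enteric-coated tablet family including one multi-parent concept, the
capsule and solution families, plus optional extra leaves), monographs
with 1–3 planted leaf dosage forms per document (probabilities
0.5/0.4/0.1, mean 1.6 — chosen to sit near the ~1.5–2 forms per
monograph typical of hand-annotated monograph collections), evidence
sentences instantiated from all five patterns, and a branded-drug table
whose product forms equal the planted sets.

Noise knobs: `route_noise` (probability a sentence uses a lay route
phrase that requires translation), `distractor_rate` (pattern-free
filler sentences), `brand_dropout` (probability the brand section is
omitted).  All output is a pure function of the spec including its
seed.

Two constructions keep the *noise-free* corpus exactly recoverable, so
that recovery failures signal implementation bugs rather than corpus
ambiguity: planted sets are antichains of leaf concepts, and two forms
are merged into one sentence only when the merged stem bag provably
matches nothing beyond what the separate sentences match.  The
bag-of-words cross-match failure mode is therefore exercised by the
dedicated worked-example tests, not hidden in the recovery corpus.
Conversely, with `route_noise = 1` and the translation rules disabled,
recall drops well below 1 — the generator is deliberately able to
demonstrate the rules' contribution.

What the generator does **not** emulate: real monograph prose variety
(templates only), misspelled or reformulated brand names, terminology
releases with hundreds of concepts, and forms mentioned outside the two
evidence sections.  Perfect scores on generated corpora therefore bound
implementation correctness, not expected real-world performance; on
real corpora the published figures for this class of method are macro
precision around 0.7–0.8 and recall 0.8–1.0 depending on the standard
used.

## Problem sizes

The test suite and the acceptance script run the worked examples on the
mini terminology (16–23 concepts), exhaustive subset checks on an
8-node oracle tree, 1,000-bag and 10,000-pair randomized property
suites, and recovery runs on 200-monograph generated corpora.  These
sizes make every check exact or effectively exhaustive at its scale.

## Known limitations

* No within-sentence association of routes with forms (bag-of-words);
  see the cross-match example above.
* The marker lexicon and translation rule set are small, hand-curated
  lists; coverage on new corpora requires extending the config files,
  not the code.
* Sentence splitting is rule-based with a fixed abbreviation stop list;
  adversarial punctuation can mis-split.
* The silver standard inherits product-level noise by design: products
  can carry forms the monograph never discusses, and vice versa, so
  silver-scored recall and precision understate performance relative to
  gold.
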