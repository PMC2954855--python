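# Methods

This note documents the models, parameters and design choices behind the
package, and what the synthetic evaluation does and does not establish.

## The extraction model

The engine rests on two assumptions. First, an intentionally weak
extraction rule — "the first thing that looks like a date", "an integer
next to a person noun" — is unreliable over a whole article but accurate
inside a single sentence already known to describe the target element.
Second, the sentence is a context both narrow enough for such rules and
broad enough for a statistical classifier to judge relevance. The engine
therefore ranks sentences per element first and applies rules only inside
the top candidates.

### Pre-processing

* **Section detection.** XML articles use explicit `<sec><title>` markup.
  For journal HTML, where heading markup varies across journals but is
  consistent within an article, the detector collects the tag signatures
  (tag-name path to the root, attributes stripped, inline formatting tags
  `b i em strong font span a sup sub u` deleted) around occurrences of cue
  phrases (Abstract, Methods, Results, …, plus common subsection cues such
  as Patients, Interventions, Outcomes, Statistical analysis) and promotes
  every block of ≤ 8 tokens sharing such a signature to a heading. Levels
  come from `hN` rank where available, else first-appearance order of the
  signature. Boundaries are approximate by design; section detection is a
  supporting step, not an evaluated component.
* **Irrelevant-section removal.** Blocks under headings in an irrelevance
  lexicon (references, bibliography, related articles, editors' notes,
  comments, footnotes, …) are dropped. Text *after* the start of the
  reference section is retained and flagged rather than dropped; flagged
  sentences are eligible candidates only for the funding elements. This
  recovers the common journal habit of placing funding statements after
  the references while keeping reference-list noise away from all other
  classifiers.
* **Sentence splitting** is terminator-based (`. ! ?` followed by
  whitespace) with protected contexts: a configurable abbreviation list
  (e.g., i.e., vs., et al., Dr., Fig., No., approx., …), decimal numbers,
  and single initials. Headings are emitted as their own one-sentence
  units so section titles participate in indexing and features.
* **Entity annotation** marks integers and reals (digit forms plus spelled
  forms one–twenty), units from a built-in lexicon, measurements
  (number + unit, e.g. "3.6 mg", "28 days"), dates (day/month/year
  patterns, years 1900–2099, normalized to a partial (year, month, day);
  a bare month name must be capitalized so the modal "may" is not tagged),
  and person nouns (patients, participants, women, …). Overlaps are
  resolved by priority (measurement > date > number > unit/person) then
  longest match, so a measurement suppresses its own number and unit and
  "March 2004" suppresses the bare-year date. Entities enter the feature
  stream as pseudo-tokens (`TAG_measurement`), equivalent for
  classification purposes to inline tagging.

### Sentence classification

Features per sentence: lowercased word unigrams, bigrams and trigrams,
entity pseudo-tokens, section-path tokens (`SEC_methods`), and a
post-reference flag token. The vocabulary is frozen at training time with
a document-frequency floor of 2; unseen test terms are dropped.

The 18 sentence-expressed elements sit in a four-level tree:
root → {population & enrolment, interventions, outcomes, funding & meta}
→ eight subgroups → leaves. The exact membership of the intermediate
nodes is a design choice (the grouping constraints leave it open); the
default tree is config-overridable and validated structurally. One binary
classifier is trained per non-root node: leaf positives are the gold
sentences of that element, internal-node positives the union over
descendants, negatives all other sentences (no subsampling;
class-imbalance handled by inverse-frequency class weights). The
classifier is a linear SVM (liblinear, C = 1 by default) — chosen for
sparse text, speed and determinism — with a monotone Platt sigmoid fitted
to the training margins to yield probabilities. A node with no positives
(e.g. early stopping in a small corpus) is marked untrainable and
contributes a neutral factor.

A sentence's confidence for a leaf is the **product** of the calibrated
probabilities along the root-to-leaf path (root excluded). The cited
top-down framework leaves the combination rule open; the product is the
standard chain choice, yields the testable invariant that leaf confidence
never exceeds any ancestor probability, and pools evidence from related
elements through the shared internal nodes. A flat (leaf-only) mode is
retained for ablation. Candidates are the top k = 5 sentences in
decreasing confidence, ties broken by earlier document position.

### Fragment extraction and post-processing

Weak rules are shipped as an editable YAML file
(`src/exact/data/default_rules.yaml`), one block per element, in a regex
dialect extended with entity placeholders (`{date}`, `{integer}`,
`{person}`, `{measurement}`, …) that match — and are verified to align
with — the sentence's annotated entity spans. Rules are tried in priority
order; capture groups named `frag…` yield the fragments, and a `take`
mode (first / last / all / all-but-last) selects among repeated matches.
The published rule inventory is not available; these starter rules are
reconstructions of the described patterns. Notable heuristics:

* Intervention enumerations ("randomly assigned to receive X … plus either
  Y or Z, with or without W") are captured by one cue-driven rule; the
  **last** enumerated intervention is taken as the control treatment and
  the others as experimental. This is a documented heuristic with a known
  failure mode — authors do not always list the control last.
* The sample-size rule requires an integer entity adjacent to a person
  noun, the date rules consume date entities (first = start, last = end),
  and the dose rule requires a measurement entity, so structural rules can
  never emit a fragment lacking its defining entity.
* Eligibility criteria are whole-sentence targets: their rule only boosts
  candidate scores and no fragments are ever highlighted.

When no rule fires on any candidate and the element is one whose values
lack surface structure (primary/secondary outcome names, experimental
treatment name), the redundancy extractor collects n-grams (orders 1–5)
shared by ≥ 2 of the top-five sentences, removes phrases made entirely of
stoplisted tokens (function words plus element boilerplate such as
"primary outcome was"), ranks survivors by length × frequency and maps the
longest non-overlapping ones back to spans in each containing sentence.

Matched candidates are boosted by `final = base + λ(1−base)` with
λ = 0.5 by default — the published description states boosting and
possible re-ordering but no formula; this form is bounded in [0, 1],
monotone, and preserves order within the matched and unmatched groups.
The suggestion is the top candidate if `final ≥ τ` (τ = 0.5 by default,
per-element override in config; the source describes the threshold only
as "very low"), else "not found". Candidates below τ carry no highlighted
fragments, resolving an ambiguity in favour of not highlighting
low-confidence text.

Cross-element linking (which dose belongs to which intervention) is out of
scope, as is any live PubMed querying: publication details are parsed from
a locally stored citation record.

## Evaluation conventions

* A suggestion is a true positive iff its sentence is a gold sentence; a
  "not found" for a gold-absent element counts as correct absence,
  excluded from the recall denominator; a (wrong) suggestion for a
  gold-absent element counts against precision.
* Exact fragment match tolerates flanking whitespace/punctuation; partial
  match is ≥ 1 character of overlap — the weakest overlap criterion,
  chosen deliberately so stricter variants remain config options.
* Micro = pooled counts, macro = unweighted mean of per-element rates;
  0/0 rates are excluded from macro means rather than coerced to 0 or 1.
* Solution categories per (document, element): fully correct (gold
  sentence on top, exact fragments, or correct absence), partially correct
  with subtypes (right sentences but wrong one on top; right top sentence
  but wrong highlighting; some gold sentences missing from the top five),
  incorrect (no gold sentence among the five). Proportions sum to 1.
* `exact.benchmarks` ships the per-element rows of a published 50-article
  evaluation of this extraction approach; running them through
  `aggregate_rates` reproduces that evaluation's macro rows (e.g.
  suggestion macro precision 0.76, fragment exact macro P/R 0.93/0.91)
  and its sentence-count-weighted micro recalls, pinning the averaging
  conventions to an external reference.

## The synthetic corpus

The generator emulates the structure the method depends on: sectioned
HTML with heading markup; per-element presence sampled at the rates of
the 50-article reference corpus (enrolment dates 0.74, registration 0.62,
funding number 0.10, early stopping 0.04, …); abstract restatement of key
facts at rate 0.3 (redundancy); 1–3 eligibility sentences
(multi-sentence rate 0.8); ~3 neutral distractor sentences per section;
and a 0.15 fraction of articles phrased so the weak rules miss,
exercising the redundancy fallback. A 0.3 fraction of funding statements
is placed after the reference list. Values are sampled from small banks
(drug names, outcome phrases, funders, doses as number + unit, month-year
dates, NCT-style identifiers). Gold indices are located by running the
package's own preprocessor over the generated article and matching the
planted sentence texts, which makes gold internally consistent by
construction; the same seed yields a byte-identical corpus.

What passing on this corpus shows: the pipeline's plumbing is correct end
to end — features carry the signal, hierarchy and calibration preserve it,
rules and redundancy find the planted spans, the metrics measure what they
claim. What it does not show: performance on real journal prose, whose
phrasing diversity, markup irregularity and annotation ambiguity the
template banks deliberately do not imitate. The recovery thresholds
asserted in the test suite (suggestion macro precision ≥ 0.80, top-5
macro recall ≥ 0.90 on a 60-train/20-test split) are sanity floors
inspired by, not asserted equal to, the published figures.

`corrupt_fragments` perturbs gold boundaries by 1–3 tokens at a chosen
rate r; evaluating gold-derived oracle results against the original gold
must then yield exact-match precision ≈ 1 − r (within binomial error)
and partial-match precision 1, calibrating the matching code itself.

## Numerical and degenerate-input choices

* All randomness flows through explicit integer seeds (corpus generation,
  SVM solver); training twice with one seed yields byte-identical model
  files, and model directories store vocabulary, per-node weights and
  metadata as JSON at full float precision.
* Empty documents and empty files are rejected with a validation error;
  a document with fewer than five sentences returns all of them, still
  ordered; a calibration fit that would invert the margin ordering is
  replaced by the identity mapping.
* Character offsets are 0-based half-open against the normalized (NFC)
  sentence text throughout.
* Problem sizes used by the shipped acceptance run — 80 generated
  articles (60 train / 20 test), ~38 sentences per article, corruption
  rate 0.3 over ~1200 fragments — keep the whole loop under a minute on
  one CPU while leaving every element trainable except the rarest
  (early stopping at presence 0.04), whose untrainable-node fallback is
  itself part of what is exercised.

## Known limitations

* The control-vs-experimental split is positional; clinical background
  knowledge is not modelled.
* Rule reconstructions cover the synthetic phrasing banks well; on real
  articles they would need the same iterative curation the originals had.
* Section detection is signature-based and approximate; deeply nested or
  CSS-styled headings without tag-level consistency will be missed (the
  sentence classifiers then simply lose section features, not sentences).
* The redundancy extractor can surface incidental shared phrases when the
  top five contains near-duplicate non-gold sentences.
* PDF and word-processor inputs are out of scope; conversion to HTML or
  text is assumed to happen upstream.
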