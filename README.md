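# exact-ie

Locating and extracting key trial characteristics — eligibility criteria,
sample size, interventions and their dose/frequency/route/duration,
outcomes, funding, registration — from full-text journal articles reporting
randomized controlled trials (RCTs). Most RCT evidence exists only as free
text; curators building systematic reviews or structured trial databases
spend hours per article transcribing these facts. This package implements
a two-stage information-extraction engine that proposes, for each of 21
information elements, the most likely sentences and the exact answer
fragments inside them, so a human reviewer only confirms or amends.

## Method

**Stage 1 — sentence classification.** Articles (journal HTML, XML with
`<sec><title>` markup, or plain text) are pre-processed: section headings
are detected by tag-signature matching around cue phrases, irrelevant
sections (reference lists, related-article blocks) are removed — with the
post-reference tail kept but flagged, because funding statements often live
there — the text is split into sentences, and common entities (numbers,
units, measurements, dates, person nouns) are annotated. Each sentence
becomes a bag of terms (word 1–3-grams, entity tags, section-path tokens).
A linear max-margin classifier with sigmoid calibration is trained for
every node of a four-level element hierarchy (semantic groups such as
*interventions* → *treatment parameters* → *dose*); a sentence's confidence
for element *e* is the product of the calibrated probabilities along the
root-to-leaf path, and the top five sentences are returned per element.

**Stage 2 — fragment extraction.** Per-element *weak rules* — deliberately
under-specific regexes over text and entity spans (the first date for an
enrolment start date, an integer next to a person noun for the sample
size, …) — highlight answer fragments inside the candidates; where no rule
fires, a redundancy extractor mines phrases repeated across the top five
sentences (outcome names, treatment names). Rule-matching candidates get a
confidence boost `s' = s + λ(1−s)` and the list is re-ranked; the top
candidate becomes the *system's suggestion* if its score clears a
threshold τ, otherwise "not found" is reported. Publication details
(first author, year, DOI) are parsed from a local PubMed-style citation
record.

**Evaluation.** Per element *i*, precision `P_i = TP_i / returned_i` and
recall `R_i = TP_i / relevant_i` at the suggestion level; top-5 recalls
(at-least-one and all-answers); fragment-level exact and partial match;
micro averages pool counts across the n = 21 elements
(`P_micro = ΣTP_i / Σreturned_i`) while macro averages are unweighted means
(`P_macro = ΣP_i / n`); and every (document, element) task is categorized
as fully correct, partially correct (wrong sentence on top / wrong
highlighting / missing sentences) or incorrect.

Because real annotated trial corpora cannot be redistributed, the package
includes a synthetic RCT-article generator (`exact.synthgen`) that emits
sectioned HTML with planted element sentences, per-element presence rates,
abstract restatement, multi-sentence eligibility criteria and neutral
distractors, with exact gold annotations — making the full train/extract/
evaluate loop reproducible from nothing.

## Worked example

```sh
exact synth --n 12 --seed 5 --out corpus        # articles + gold
exact train --corpus corpus --gold corpus --out model --seed 5
exact run corpus/synth0000.html --model model --out corpus/synth0000.results.json
exact eval --results corpus --gold corpus --out report.json
```

prints

```
wrote 12 articles to corpus
trained 28 node models
13/21 elements located -> corpus/synth0000.results.json
suggestion macro P/R = 0.92/1.00
```

"13/21 elements located" means 13 elements cleared the not-found threshold
for this article — the remainder are genuinely absent from it (and the
three publication details need `--citation`). The results JSON holds, per
element, the five ranked candidates with base and final scores and
highlighted fragment intervals, e.g. for the enrolment start date:

```json
{
  "suggestion_index": 15,
  "candidates": [
    {
      "sentence_index": 15,
      "text": "Patients were recruited between May 1995 and July 1997.",
      "base_score": 0.9966,
      "final_score": 0.9983,
      "fragments": [[32, 40]]
    }
  ]
}
```

The fragment `[32, 40)` is `"May 1995"` — the first date entity, as the
start-date rule prescribes; the score was boosted from 0.9966 because the
rule matched. `exact eval` then scores such results against gold: here the
suggestion is correct in 92% of element tasks (macro precision) and every
present element had a relevant sentence suggested (macro recall 1.00).

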