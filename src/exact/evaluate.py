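"""Evaluation: sentence- and fragment-level precision/recall, aggregation,
and solution categorization.

Sentence level: the *system's suggestion* (the single top candidate, or an
explicit "not found") is scored per element — a suggestion is a true
positive iff its sentence is a gold sentence; a "not found" for an element
absent from gold counts as a correct confirmation of absence and is excluded
from the recall denominator.  Top-5 quality is measured two ways: the
fraction of gold-present (document, element) pairs with at least one gold
sentence among the five candidates, and the fraction of all gold sentences
recovered in top-5 lists.

Fragment level: restricted to candidates whose sentence is gold-relevant.
Exact match means the predicted interval equals the gold interval after
trimming flanking whitespace/punctuation; partial match means an overlap of
at least one character.

Aggregation follows the two standard conventions: micro-averaging pools
counts across elements before forming the ratio; macro-averaging takes the
unweighted mean of per-element rates (0/0 elements are excluded from the
mean and reported as absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .extract import ElementResult
from .io import GoldAnnotation
from .schema import ElementSpec, MODE_CITATION, MODE_WHOLE_SENTENCE

__all__ = [
    "ElementCounts",
    "EvalReport",
    "sentence_metrics",
    "fragment_metrics",
    "aggregate_micro_macro",
    "aggregate_rates",
    "categorize_solutions",
    "evaluate_corpus",
]

Interval = Tuple[int, int]
ResultsByDoc = Mapping[str, Mapping[str, ElementResult]]
GoldByDoc = Mapping[str, GoldAnnotation]

_TRIM_CHARS = " \t\r\n.,;:()[]{}\"'"


@dataclass
class ElementCounts:
    """Per-element tallies: TP <= min(returned, relevant)."""

    element_id: str
    tp: int = 0
    returned: int = 0
    relevant: int = 0

    @property
    def precision(self) -> Optional[float]:
        return self.tp / self.returned if self.returned else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / self.relevant if self.relevant else None


def _check_same_docs(results: ResultsByDoc, gold: GoldByDoc) -> None:
    if set(results) != set(gold):
        raise ValueError(
            "results and gold cover different documents: "
            f"{sorted(set(results) ^ set(gold))[:5]}"
        )


def _gold_sentences(g: GoldAnnotation, eid: str) -> List[int]:
    return [a.sentence_index for a in g.for_element(eid)]


def sentence_metrics(
    results: ResultsByDoc,
    gold: GoldByDoc,
    specs: Sequence[ElementSpec],
    k: int = 5,
) -> Dict[str, dict]:
    """Suggestion-level counts plus top-k recalls, per element.

    Returns per element-id a dict with an :class:`ElementCounts`, the
    correct-absence count, and numerator/denominator pairs for the top-k
    at-least-one and all-answers recalls.
    """
    _check_same_docs(results, gold)
    out: Dict[str, dict] = {}
    for spec in specs:
        if spec.extraction_mode == MODE_CITATION:
            continue
        eid = spec.element_id
        counts = ElementCounts(eid)
        correct_absence = 0
        atleast_num = atleast_den = 0
        all_num = all_den = 0
        for doc_id, res_map in results.items():
            res = res_map.get(eid)
            g = _gold_sentences(gold[doc_id], eid)
            sugg = res.suggestion_index if res is not None else None
            if g:
                counts.relevant += 1
                if sugg is not None:
                    counts.returned += 1
                    if sugg in g:
                        counts.tp += 1
                topk = [c.sentence_index for c in res.candidates[:k]] if res else []
                atleast_den += 1
                if any(s in topk for s in g):
                    atleast_num += 1
                all_den += len(g)
                all_num += sum(1 for s in g if s in topk)
            else:
                if sugg is None:
                    correct_absence += 1
                else:
                    counts.returned += 1  # wrong suggestion for an absent element
        out[eid] = {
            "counts": counts,
            "correct_absence": correct_absence,
            "top_k_at_least_one": (atleast_num, atleast_den),
            "top_k_all_answers": (all_num, all_den),
        }
    return out


# ---------------------------------------------------------------------------
# fragment level


def _trim(interval: Interval, text: str) -> Interval:
    s, e = interval
    e = min(e, len(text))
    while s < e and text[s] in _TRIM_CHARS:
        s += 1
    while e > s and text[e - 1] in _TRIM_CHARS:
        e -= 1
    return (s, e)


def _frag_match(pred: Interval, g: Interval, text: str, mode: str) -> bool:
    if mode == "exact":
        return _trim(pred, text) == _trim(g, text)
    if mode == "partial":
        return pred[0] < g[1] and pred[1] > g[0]
    raise ValueError(f"unknown match mode {mode!r}")


def fragment_metrics(
    results: ResultsByDoc,
    gold: GoldByDoc,
    specs: Sequence[ElementSpec],
    mode: str = "exact",
    k: int = 5,
) -> Dict[str, ElementCounts]:
    """Fragment-level precision/recall, restricted to gold-relevant candidates.

    For every top-k candidate whose sentence is a gold sentence, the
    predicted intervals are matched against that sentence's gold fragments.
    ``tp`` counts matched predictions; ``returned`` all predictions;
    ``relevant`` all gold fragments on sentences that reached the top-k.
    """
    _check_same_docs(results, gold)
    out: Dict[str, ElementCounts] = {}
    for spec in specs:
        if spec.extraction_mode in (MODE_CITATION, MODE_WHOLE_SENTENCE):
            continue
        eid = spec.element_id
        counts = ElementCounts(eid)
        for doc_id, res_map in results.items():
            res = res_map.get(eid)
            if res is None:
                continue
            gold_by_sentence = {
                a.sentence_index: list(a.fragments)
                for a in gold[doc_id].for_element(eid)
            }
            for c in res.candidates[:k]:
                gfrags = gold_by_sentence.get(c.sentence_index)
                if gfrags is None:
                    continue
                counts.returned += len(c.fragments)
                counts.relevant += len(gfrags)
                matched_gold = set()
                for p in c.fragments:
                    hit = next(
                        (
                            i
                            for i, gf in enumerate(gfrags)
                            if i not in matched_gold
                            and _frag_match(p, gf, c.text, mode)
                        ),
                        None,
                    )
                    if hit is not None:
                        matched_gold.add(hit)
                        counts.tp += 1
        out[eid] = counts
    return out


# ---------------------------------------------------------------------------
# aggregation


def aggregate_micro_macro(counts: Iterable[ElementCounts]) -> Dict[str, Optional[float]]:
    """Micro (pooled counts) and macro (mean of rates) precision and recall."""
    counts = list(counts)
    tp = sum(c.tp for c in counts)
    ret = sum(c.returned for c in counts)
    rel = sum(c.relevant for c in counts)
    precisions = [c.precision for c in counts if c.precision is not None]
    recalls = [c.recall for c in counts if c.recall is not None]
    return {
        "micro_precision": tp / ret if ret else None,
        "micro_recall": tp / rel if rel else None,
        "macro_precision": sum(precisions) / len(precisions) if precisions else None,
        "macro_recall": sum(recalls) / len(recalls) if recalls else None,
    }


def aggregate_rates(
    rates: Sequence[float], weights: Optional[Sequence[float]] = None
) -> Dict[str, Optional[float]]:
    """Macro (unweighted mean) and micro (denominator-weighted mean) of
    per-element rates."""
    vals = [r for r in rates if r is not None]
    macro = sum(vals) / len(vals) if vals else None
    micro = None
    if weights is not None:
        pairs = [(r, w) for r, w in zip(rates, weights) if r is not None and w]
        tot = sum(w for _, w in pairs)
        micro = sum(r * w for r, w in pairs) / tot if tot else None
    return {"macro": macro, "micro": micro}


# ---------------------------------------------------------------------------
# solution categories


CATEGORIES = (
    "fully_correct",
    "sentence_selection_only",
    "change_in_highlighting",
    "sentence_adding",
    "incorrect",
)


def _fragments_exact(res: ElementResult, gold_by_sentence, whole_sentence: bool, k: int) -> bool:
    for c in res.candidates[:k]:
        gfrags = gold_by_sentence.get(c.sentence_index)
        if gfrags is None:
            continue
        if whole_sentence:
            continue  # whole-sentence targets carry no fragments
        pred = sorted(_trim(p, c.text) for p in c.fragments)
        want = sorted(_trim(g, c.text) for g in gfrags)
        if pred != want:
            return False
    return True


def categorize_solutions(
    results: ResultsByDoc,
    gold: GoldByDoc,
    specs: Sequence[ElementSpec],
    k: int = 5,
) -> Dict[str, Dict[str, float]]:
    """Per-element proportions of fully / partially / incorrect solutions.

    fully_correct: the top-scored suggestion is a gold sentence, every gold
    sentence is in the top-k, fragments match exactly — or a correct "not
    found".  Partially correct splits into: right sentences present but the
    wrong one on top; right top sentence but wrong highlighting; some gold
    sentences missing from the top-k.  Incorrect: no gold sentence among the
    five (or a suggestion for an element absent in gold).
    """
    _check_same_docs(results, gold)
    out: Dict[str, Dict[str, float]] = {}
    for spec in specs:
        if spec.extraction_mode == MODE_CITATION:
            continue
        eid = spec.element_id
        tally = {c: 0 for c in CATEGORIES}
        n = 0
        whole = spec.extraction_mode == MODE_WHOLE_SENTENCE
        for doc_id, res_map in results.items():
            res = res_map.get(eid) or ElementResult(eid)
            g = _gold_sentences(gold[doc_id], eid)
            gold_by_sentence = {
                a.sentence_index: list(a.fragments)
                for a in gold[doc_id].for_element(eid)
            }
            n += 1
            if not g:
                tally["fully_correct" if res.suggestion_index is None else "incorrect"] += 1
                continue
            topk = [c.sentence_index for c in res.candidates[:k]]
            in_top = [s for s in g if s in topk]
            if not in_top:
                tally["incorrect"] += 1
            elif len(in_top) < len(g):
                tally["sentence_adding"] += 1
            elif res.suggestion_index not in g:
                tally["sentence_selection_only"] += 1
            elif not _fragments_exact(res, gold_by_sentence, whole, k):
                tally["change_in_highlighting"] += 1
            else:
                tally["fully_correct"] += 1
        out[eid] = {c: (tally[c] / n if n else 0.0) for c in CATEGORIES}
        out[eid]["partially_correct"] = (
            out[eid]["sentence_selection_only"]
            + out[eid]["change_in_highlighting"]
            + out[eid]["sentence_adding"]
        )
    return out


# ---------------------------------------------------------------------------
# full report


@dataclass
class EvalReport:
    sentence: Dict[str, dict]
    fragment_exact: Dict[str, ElementCounts]
    fragment_partial: Dict[str, ElementCounts]
    categories: Dict[str, Dict[str, float]]
    aggregates: Dict[str, Optional[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        per_element = {}
        for eid, s in self.sentence.items():
            c: ElementCounts = s["counts"]
            a_num, a_den = s["top_k_at_least_one"]
            l_num, l_den = s["top_k_all_answers"]
            fe = self.fragment_exact.get(eid)
            fp = self.fragment_partial.get(eid)
            per_element[eid] = {
                "suggestion_precision": c.precision,
                "suggestion_recall": c.recall,
                "correct_absence": s["correct_absence"],
                "top5_at_least_one_recall": a_num / a_den if a_den else None,
                "top5_all_answers_recall": l_num / l_den if l_den else None,
                "fragment_exact_precision": fe.precision if fe else None,
                "fragment_exact_recall": fe.recall if fe else None,
                "fragment_partial_precision": fp.precision if fp else None,
                "fragment_partial_recall": fp.recall if fp else None,
                "categories": self.categories.get(eid),
            }
        return {"per_element": per_element, "aggregates": self.aggregates}


def evaluate_corpus(
    results: ResultsByDoc,
    gold: GoldByDoc,
    specs: Sequence[ElementSpec],
    k: int = 5,
) -> EvalReport:
    """Compute the full report over a result/gold corpus pair."""
    sent = sentence_metrics(results, gold, specs, k=k)
    frag_e = fragment_metrics(results, gold, specs, mode="exact", k=k)
    frag_p = fragment_metrics(results, gold, specs, mode="partial", k=k)
    cats = categorize_solutions(results, gold, specs, k=k)

    sugg = aggregate_micro_macro(s["counts"] for s in sent.values())
    atleast = [
        (s["top_k_at_least_one"][0] / s["top_k_at_least_one"][1])
        if s["top_k_at_least_one"][1]
        else None
        for s in sent.values()
    ]
    weights = [s["top_k_at_least_one"][1] for s in sent.values()]
    all_r = [
        (s["top_k_all_answers"][0] / s["top_k_all_answers"][1])
        if s["top_k_all_answers"][1]
        else None
        for s in sent.values()
    ]
    all_w = [s["top_k_all_answers"][1] for s in sent.values()]
    agg = {
        "suggestion_micro_precision": sugg["micro_precision"],
        "suggestion_micro_recall": sugg["micro_recall"],
        "suggestion_macro_precision": sugg["macro_precision"],
        "suggestion_macro_recall": sugg["macro_recall"],
        "top5_macro_recall": aggregate_rates(atleast)["macro"],
        "top5_micro_recall": aggregate_rates(atleast, weights)["micro"],
        "all_answers_macro_recall": aggregate_rates(all_r)["macro"],
        "all_answers_micro_recall": aggregate_rates(all_r, all_w)["micro"],
    }
    for mode, table in (("exact", frag_e), ("partial", frag_p)):
        fa = aggregate_micro_macro(table.values())
        agg[f"fragment_{mode}_micro_precision"] = fa["micro_precision"]
        agg[f"fragment_{mode}_micro_recall"] = fa["micro_recall"]
        agg[f"fragment_{mode}_macro_precision"] = fa["macro_precision"]
        agg[f"fragment_{mode}_macro_recall"] = fa["macro_recall"]
    fully = [c["fully_correct"] for c in cats.values()]
    agg["fully_correct_macro"] = aggregate_rates(fully)["macro"]
    partial = [c["partially_correct"] for c in cats.values()]
    agg["partially_correct_macro"] = aggregate_rates(partial)["macro"]
    return EvalReport(
        sentence=sent,
        fragment_exact=frag_e,
        fragment_partial=frag_p,
        categories=cats,
        aggregates=agg,
    )
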