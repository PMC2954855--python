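from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from exact.classify import Candidate
from exact.evaluate import (
    ElementCounts,
    aggregate_micro_macro,
    aggregate_rates,
    categorize_solutions,
    evaluate_corpus,
    fragment_metrics,
    sentence_metrics,
)
from exact.extract import ElementResult
from exact.io import GoldAnnotation, GoldAnswer
from exact.schema import default_schema

SPECS, _ = default_schema()


def test_micro_macro_worked_example():
    counts = [
        ElementCounts("a", tp=1, returned=2, relevant=2),
        ElementCounts("b", tp=3, returned=3, relevant=3),
    ]
    agg = aggregate_micro_macro(counts)
    assert agg["micro_precision"] == pytest.approx(4 / 5)
    assert agg["macro_precision"] == pytest.approx(0.75)


def test_all_perfect_micro_equals_macro():
    counts = [ElementCounts(str(i), tp=n, returned=n, relevant=n) for i, n in enumerate([3, 7, 1])]
    agg = aggregate_micro_macro(counts)
    assert agg["micro_precision"] == agg["macro_precision"] == 1.0
    assert agg["micro_recall"] == agg["macro_recall"] == 1.0


@settings(max_examples=1000, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=50),  # returned
            st.integers(min_value=0, max_value=50),  # relevant
            st.integers(min_value=0, max_value=50),  # tp cap
        ),
        min_size=1,
        max_size=21,
    )
)
def test_micro_macro_equal_brute_force(raw):
    """Formula output equals exact-rational pooled/mean computation."""
    counts = [
        ElementCounts(str(i), tp=min(t, r1, r2), returned=r1, relevant=r2)
        for i, (r1, r2, t) in enumerate(raw)
    ]
    agg = aggregate_micro_macro(counts)
    ret = sum(c.returned for c in counts)
    rel = sum(c.relevant for c in counts)
    if ret:
        micro_p = Fraction(sum(c.tp for c in counts), ret)
        assert agg["micro_precision"] == pytest.approx(float(micro_p))
    else:
        assert agg["micro_precision"] is None
    if rel:
        micro_r = Fraction(sum(c.tp for c in counts), rel)
        assert agg["micro_recall"] == pytest.approx(float(micro_r))
    ps = [Fraction(c.tp, c.returned) for c in counts if c.returned]
    if ps:
        assert agg["macro_precision"] == pytest.approx(float(sum(ps) / len(ps)))
    else:
        assert agg["macro_precision"] is None


def test_aggregate_rates_weighted():
    out = aggregate_rates([1.0, 0.5], weights=[1, 3])
    assert out["macro"] == pytest.approx(0.75)
    assert out["micro"] == pytest.approx((1.0 + 1.5) / 4)


def _result(eid, cand_indices, frags=None, suggestion=None, texts=None):
    cands = []
    for rank, i in enumerate(cand_indices):
        text = (texts or {}).get(i, "x" * 40)
        cands.append(
            Candidate(
                sentence_index=i,
                text=text,
                base_score=1.0 - rank * 0.1,
                final_score=1.0 - rank * 0.1,
                fragments=tuple((frags or {}).get(i, ())),
            )
        )
    return ElementResult(element_id=eid, candidates=cands, suggestion_index=suggestion)


def _gold(doc_id, eid, answers):
    return GoldAnnotation(
        doc_id=doc_id,
        answers={eid: [GoldAnswer(i, tuple(f)) for i, f in answers]},
    )


def test_sentence_metrics_counts_and_topk():
    """Three gold eligibility sentences, two in the top five: contributes
    2/3 to all-answers recall and 1 to at-least-one recall."""
    eid = "eligibility_criteria"
    results = {"d": {eid: _result(eid, [4, 9, 2, 7, 1], suggestion=4)}}
    gold = {"d": _gold("d", eid, [(4, ()), (9, ()), (30, ())])}
    m = sentence_metrics(results, gold, SPECS)[eid]
    assert m["counts"].tp == 1 and m["counts"].returned == 1 and m["counts"].relevant == 1
    assert m["top_k_at_least_one"] == (1, 1)
    assert m["top_k_all_answers"] == (2, 3)


def test_sentence_metrics_correct_absence_excluded_from_recall():
    eid = "sample_size"
    results = {"d": {eid: ElementResult(eid)}}
    gold = {"d": GoldAnnotation("d", {})}
    m = sentence_metrics(results, gold, SPECS)[eid]
    assert m["correct_absence"] == 1
    assert m["counts"].relevant == 0 and m["counts"].returned == 0


def test_sentence_metrics_wrong_suggestion_for_absent_element_penalizes_precision():
    eid = "sample_size"
    results = {"d": {eid: _result(eid, [3], suggestion=3)}}
    gold = {"d": GoldAnnotation("d", {})}
    m = sentence_metrics(results, gold, SPECS)[eid]
    assert m["counts"].returned == 1 and m["counts"].tp == 0


def test_sentence_metrics_document_mismatch():
    with pytest.raises(ValueError):
        sentence_metrics({"a": {}}, {"b": GoldAnnotation("b", {})}, SPECS)


def test_fragment_exact_vs_partial():
    eid = "experimental_treatment_name"
    text = "to receive either tamoxifen daily"
    # gold: "tamoxifen" [18, 27); prediction overshoots to "either tamoxifen"
    results = {
        "d": {
            eid: _result(
                eid, [0], frags={0: [(11, 27)]}, suggestion=0, texts={0: text}
            )
        }
    }
    gold = {"d": _gold("d", eid, [(0, [(18, 27)])])}
    exact = fragment_metrics(results, gold, SPECS, mode="exact")[eid]
    partial = fragment_metrics(results, gold, SPECS, mode="partial")[eid]
    assert (exact.tp, exact.returned, exact.relevant) == (0, 1, 1)
    assert (partial.tp, partial.returned, partial.relevant) == (1, 1, 1)


def test_fragment_exact_tolerates_flanking_punctuation():
    eid = "funding_organization_name"
    text = "supported by the Wellcome Trust."
    results = {
        "d": {eid: _result(eid, [0], frags={0: [(17, 32)]}, suggestion=0, texts={0: text})}
    }  # prediction includes the trailing period
    gold = {"d": _gold("d", eid, [(0, [(17, 31)])])}
    exact = fragment_metrics(results, gold, SPECS, mode="exact")[eid]
    assert exact.tp == 1


def test_fragment_disjoint_no_match_either_mode():
    eid = "dose"
    text = "doses of 20 mg and 50 mg were compared"
    results = {
        "d": {eid: _result(eid, [0], frags={0: [(9, 14)]}, suggestion=0, texts={0: text})}
    }
    gold = {"d": _gold("d", eid, [(0, [(19, 24)])])}
    for mode in ("exact", "partial"):
        c = fragment_metrics(results, gold, SPECS, mode=mode)[eid]
        assert c.tp == 0


def test_categorize_solutions_paths():
    eid = "sample_size"
    text = "A total of 120 patients were enrolled"
    frag = (11, 23)

    def gold_for(idx):
        return {"d": _gold("d", eid, [(idx, [frag])])}

    # gold on top with exact fragment -> fully correct
    res = {"d": {eid: _result(eid, [5, 6], frags={5: [frag]}, suggestion=5, texts={5: text})}}
    cats = categorize_solutions(res, gold_for(5), SPECS)[eid]
    assert cats["fully_correct"] == 1.0

    # gold ranked third with exact fragments -> sentence selection only
    res = {"d": {eid: _result(eid, [7, 8, 5], frags={5: [frag]}, suggestion=7, texts={5: text})}}
    cats = categorize_solutions(res, gold_for(5), SPECS)[eid]
    assert cats["sentence_selection_only"] == 1.0
    assert cats["partially_correct"] == 1.0

    # gold on top, wrong highlighting
    res = {"d": {eid: _result(eid, [5], frags={5: [(0, 6)]}, suggestion=5, texts={5: text})}}
    cats = categorize_solutions(res, gold_for(5), SPECS)[eid]
    assert cats["change_in_highlighting"] == 1.0

    # element present but no gold sentence in the top five -> incorrect
    res = {"d": {eid: _result(eid, [1, 2, 3, 4, 6], suggestion=1)}}
    cats = categorize_solutions(res, gold_for(9), SPECS)[eid]
    assert cats["incorrect"] == 1.0


def test_category_proportions_sum_to_one(synth_loop):
    cats = categorize_solutions(
        synth_loop["results"], synth_loop["gold_map"], SPECS
    )
    for eid, c in cats.items():
        total = c["fully_correct"] + c["partially_correct"] + c["incorrect"]
        assert total == pytest.approx(1.0)


def test_top5_recall_dominates_suggestion_recall(synth_loop):
    """The suggestion is drawn from the top five, so per element the top-5
    at-least-one recall is at least the suggestion recall."""
    m = sentence_metrics(synth_loop["results"], synth_loop["gold_map"], SPECS)
    for eid, s in m.items():
        r = s["counts"].recall
        num, den = s["top_k_at_least_one"]
        if r is not None and den:
            assert num / den >= r - 1e-12


def test_evaluate_corpus_report_structure(synth_loop):
    rep = evaluate_corpus(synth_loop["results"], synth_loop["gold_map"], SPECS)
    d = rep.to_dict()
    assert set(d) == {"per_element", "aggregates"}
    assert "sample_size" in d["per_element"]
    assert d["aggregates"]["suggestion_macro_precision"] is not None
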