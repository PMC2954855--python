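import pytest
from hypothesis import given, settings, strategies as st

from exact.classify import Candidate
from exact.extract import (
    apply_weak_rules,
    boost_and_rerank,
    default_rules,
    redundancy_extract,
    run_pipeline,
)
from exact.preprocess import Sentence, annotate_entities
from exact.schema import SchemaError, default_schema

RULES = default_rules()
SPECS, _ = default_schema()


def _sentence(text, index=0):
    return Sentence(
        index=index,
        text=text,
        doc_span=(0, len(text)),
        entities=tuple(annotate_entities(text)),
    )


def _frag_texts(eid, text):
    s = _sentence(text)
    c = Candidate(0, text, 0.9, 0.9)
    return [text[a:b] for a, b in apply_weak_rules(RULES[eid], eid, c, s)]


def test_every_rules_mode_element_has_a_rule():
    for spec in SPECS:
        if spec.extraction_mode == "rules":
            assert RULES.get(spec.element_id), spec.element_id


def test_intervention_enumeration_rule():
    """Drug names after the assignment cues are captured; the last
    enumerated intervention is treated as the control arm."""
    text = (
        "Patients were randomly assigned (in a 1:1:1:1 ratio with the use of "
        "a two-by-two factorial design) to receive goserelin (3.6 mg given "
        "subcutaneously every 28 days) plus either tamoxifen (20 mg per day "
        "given orally) or anastrozole (1 mg per day given orally), with or "
        "without zoledronic acid (initially 8 mg given intravenously every 4 "
        "weeks)."
    )
    exp = _frag_texts("experimental_treatment_name", text)
    ctrl = _frag_texts("control_treatment_name", text)
    assert exp == ["goserelin", "tamoxifen", "anastrozole"]
    assert ctrl == ["zoledronic acid"]
    assert set(exp) | set(ctrl) == {
        "goserelin", "tamoxifen", "anastrozole", "zoledronic acid",
    }


def test_sample_size_rule_integer_with_person():
    assert _frag_texts("sample_size", "A total of 120 patients were enrolled") == [
        "120 patients"
    ]


def test_date_rule_requires_date_entity():
    assert _frag_texts("start_date_of_enrolment", "No dates appear here at all.") == []


def test_date_rules_first_and_last():
    text = "Patients were recruited between March 2004 and May 2006."
    assert _frag_texts("start_date_of_enrolment", text) == ["March 2004"]
    assert _frag_texts("end_date_of_enrolment", text) == ["May 2006"]


def test_structural_fragments_contain_their_entity():
    """A date fragment contains a date span; a dose fragment a measurement."""
    text = "Enrolment began in March 2004 and treatment used 2.5 mg doses."
    s = _sentence(text)
    for eid in ("start_date_of_enrolment", "dose"):
        c = Candidate(0, text, 0.9, 0.9)
        kind = "date" if "date" in eid else "measurement"
        spans = [e.span for e in s.entities if e.kind == kind]
        for f in apply_weak_rules(RULES[eid], eid, c, s):
            assert any(f[0] <= a and f[1] >= b for a, b in spans if a >= f[0] or b <= f[1])
            assert any(f[0] < b and f[1] > a for a, b in spans)


def test_redundancy_extracts_shared_phrase():
    texts = [
        "Efficacy was evaluated using overall survival in all randomized participants.",
        "Treatment effects on overall survival were examined during follow-up.",
        "Baseline characteristics were similar between the groups.",
        "The protocol was approved by the local ethics committee.",
        "Missing values were handled with multiple imputation.",
    ]
    sentences = {i: _sentence(t, i) for i, t in enumerate(texts)}
    cands = [Candidate(i, t, 0.8, 0.8) for i, t in enumerate(texts)]
    hits = redundancy_extract("primary_outcome_name", cands, sentences)
    got = {
        c.sentence_index: [texts[c.sentence_index][a:b] for a, b in frags]
        for c, frags in hits
    }
    assert got[0] == ["overall survival"]
    assert got[1] == ["overall survival"]
    assert 2 not in got


def test_redundancy_no_shared_phrase_and_stoplisted_phrase():
    texts = [
        "Alpha beta gamma delta.",
        "Epsilon zeta eta theta.",
    ]
    sentences = {i: _sentence(t, i) for i, t in enumerate(texts)}
    cands = [Candidate(i, t, 0.8, 0.8) for i, t in enumerate(texts)]
    assert redundancy_extract("primary_outcome_name", cands, sentences) == []

    texts = [
        "The primary outcome was assessed.",
        "The primary outcome was measured.",
    ]
    sentences = {i: _sentence(t, i) for i, t in enumerate(texts)}
    cands = [Candidate(i, t, 0.8, 0.8) for i, t in enumerate(texts)]
    assert redundancy_extract("primary_outcome_name", cands, sentences) == []


def test_redundancy_rejected_for_structured_elements():
    with pytest.raises(SchemaError):
        redundancy_extract("dose", [], {})


def test_boost_reranks_matched_candidate():
    c1 = Candidate(1, "no match", 0.70, 0.70)
    c2 = Candidate(2, "match", 0.65, 0.65)
    out = boost_and_rerank([c1, c2], matched={2}, lam=0.5)
    assert [c.sentence_index for c in out] == [2, 1]
    assert out[0].final_score == pytest.approx(0.825)
    assert out[1].final_score == 0.70


def test_boost_identity_without_matches():
    cands = [Candidate(i, "", s, s) for i, s in enumerate([0.9, 0.5, 0.3])]
    out = boost_and_rerank(cands, matched=set())
    assert [c.sentence_index for c in out] == [0, 1, 2]
    assert all(c.final_score == c.base_score for c in out)


def test_boost_fixed_point_at_one():
    c = Candidate(0, "", 1.0, 1.0)
    out = boost_and_rerank([c], matched={0})
    assert out[0].final_score == 1.0


@settings(max_examples=200, derandomize=True)
@given(
    scores=st.lists(
        # hundredth grid keeps ties exact under the boost transform
        st.integers(min_value=0, max_value=100).map(lambda v: v / 100),
        min_size=1,
        max_size=8,
    ),
    mask=st.lists(st.booleans(), min_size=8, max_size=8),
    lam=st.floats(min_value=0.05, max_value=0.95),
)
def test_boost_monotone_bounded_order_preserving(scores, mask, lam):
    cands = [Candidate(i, "", s, s) for i, s in enumerate(scores)]
    matched = {i for i, m in enumerate(mask[: len(scores)]) if m}
    out = boost_and_rerank(cands, matched, lam=lam)
    by_idx = {c.sentence_index: c for c in out}
    for c in cands:
        f = by_idx[c.sentence_index].final_score
        assert c.base_score <= f <= 1.0 + 1e-12
        if c.sentence_index not in matched:
            assert f == c.base_score
    # order preserved within the matched and unmatched groups
    for group in (matched, set(range(len(scores))) - matched):
        ranks = [c.sentence_index for c in out if c.sentence_index in group]
        base_sorted = sorted(
            group, key=lambda i: (-scores[i], i)
        )
        assert ranks == base_sorted


def test_pipeline_end_to_end_highlights_planted_date(synth_loop):
    """A planted enrolment-date sentence is suggested with its first date
    highlighted, and missing elements report not-found."""
    found_date = absent_checked = 0
    for doc_id, results in synth_loop["results"].items():
        gold = synth_loop["gold_map"][doc_id]
        res = results["start_date_of_enrolment"]
        g = gold.for_element("start_date_of_enrolment")
        if g and res.suggestion_index is not None:
            if res.suggestion_index == g[0].sentence_index:
                sugg = res.suggestion
                if sugg.fragments:
                    assert sugg.fragments[0] == g[0].fragments[0]
                    found_date += 1
        if not gold.for_element("trial_registration_id"):
            assert results["trial_registration_id"].suggestion_index is None
            absent_checked += 1
    assert found_date >= 5
    assert absent_checked >= 1


def test_pipeline_eligibility_never_carries_fragments(synth_loop):
    for results in synth_loop["results"].values():
        for c in results["eligibility_criteria"].candidates:
            assert c.fragments == ()


def test_pipeline_candidate_invariants(synth_loop):
    for results in synth_loop["results"].values():
        for res in results.values():
            finals = [c.final_score for c in res.candidates]
            assert finals == sorted(finals, reverse=True)
            assert len(res.candidates) <= 5
            for c in res.candidates:
                assert c.final_score >= c.base_score - 1e-12
                for a, b in c.fragments:
                    assert 0 <= a < b <= len(c.text)


def test_pipeline_citation_elements(synth_loop, schema):
    from exact.extract import run_pipeline
    from exact.io import CitationRecord

    specs, _ = schema
    doc = synth_loop["annotated"][60]
    cit = CitationRecord("Jane Smith", 2009, "10.1186/x")
    results = run_pipeline(
        synth_loop["model"], synth_loop["rules"], doc, specs, citation=cit
    )
    assert results["author_name"].value == "Jane Smith"
    assert results["date_of_publication"].value == "2009"
    assert results["doi"].value == "10.1186/x"
    no_cit = synth_loop["results"][doc.doc_id]
    assert no_cit["doi"].not_found


def test_pipeline_deterministic(synth_loop, schema):
    specs, _ = schema
    doc = synth_loop["annotated"][60]
    r1 = synth_loop["results"][doc.doc_id]
    r2 = run_pipeline(synth_loop["model"], synth_loop["rules"], doc, specs)
    for eid in r1:
        assert r1[eid].suggestion_index == r2[eid].suggestion_index
        assert [c.final_score for c in r1[eid].candidates] == [
            c.final_score for c in r2[eid].candidates
        ]
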