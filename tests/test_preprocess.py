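import pytest

from exact.io import RawDocument
from exact.preprocess import (
    annotate_entities,
    detect_sections,
    preprocess_document,
    split_sentences,
)

XML_DOC = RawDocument(
    doc_id="x",
    format="xml",
    content=(
        '<?xml version="1.0"?><article>'
        "<sec><title>Methods</title><p>First methods sentence.</p>"
        "<sec><title>Patients</title><p>Patients were screened.</p></sec></sec>"
        "</article>"
    ),
)

HTML_DOC = RawDocument(
    doc_id="h",
    format="html",
    content=(
        "<html><body>"
        "<h2 class='s'>Abstract</h2><p>Summary sentence.</p>"
        "<h2 class='s'>Methods</h2><p>Method detail.</p>"
        "<h2 class='s'>Statistical analysis</h2><p>Analysis detail.</p>"
        "<h2 class='s'>Results</h2><p>The <b>results</b> were clear.</p>"
        "</body></html>"
    ),
)


def test_xml_sections_follow_markup():
    secs = detect_sections(XML_DOC)
    by_name = {s.heading_text: s for s in secs}
    assert by_name["Methods"].level == 1
    assert by_name["Patients"].level == 2
    assert by_name["Patients"].parent is by_name["Methods"]


def test_html_signature_sharing_promotes_same_level_headings():
    """'Statistical analysis' is formatted like the cue headings, so it
    becomes a heading of the same level, while an incidental bolded word
    inside a paragraph does not."""
    secs = detect_sections(HTML_DOC)
    names = {s.heading_text for s in secs}
    assert "Statistical analysis" in names
    assert {s.level for s in secs} == {1}
    assert all("results were clear" not in s.heading_text for s in secs)
    # the <b>results</b> paragraph is content, not a heading
    ann = preprocess_document(HTML_DOC)
    texts = [s.text for s in ann.sentences if not s.is_heading]
    assert "The results were clear." in texts


def test_plain_text_gets_single_implicit_section():
    doc = RawDocument(doc_id="t", format="text", content="One sentence. Two sentences.")
    assert len(detect_sections(doc)) == 1
    ann = preprocess_document(doc)
    assert len(ann.sentences) == 2
    assert all(s.section_path == () for s in ann.sentences)


def test_references_removed_post_reference_tail_flagged():
    doc = RawDocument(
        doc_id="r",
        format="html",
        content=(
            "<html><body><h2>Methods</h2><p>Drug was given.</p>"
            "<h2>References</h2><p>1. Old trial. 1999.</p>"
            "<h2>Funding</h2><p>This study was funded by the Wellcome Trust.</p>"
            "</body></html>"
        ),
    )
    ann = preprocess_document(doc)
    texts = {s.text: s for s in ann.sentences}
    assert not any("Old trial" in t for t in texts)
    fund = texts["This study was funded by the Wellcome Trust."]
    assert fund.post_reference_flag
    assert not texts["Drug was given."].post_reference_flag


def test_related_articles_block_removed():
    doc = RawDocument(
        doc_id="ra",
        format="html",
        content=(
            "<html><body><h2>Results</h2><p>Outcome improved.</p>"
            "<h2>Related articles</h2><p>See also this other study.</p>"
            "</body></html>"
        ),
    )
    # "Related articles" shares the h2 signature with the cue "Results"
    ann = preprocess_document(doc)
    assert not any("other study" in s.text for s in ann.sentences)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("The dose was 2.5 mg. Patients improved.", ["The dose was 2.5 mg.", "Patients improved."]),
        ("Criteria (e.g. diabetes) were applied.", ["Criteria (e.g. diabetes) were applied."]),
        ("", []),
        ("Dr. Smith approved. The rest followed.", ["Dr. Smith approved.", "The rest followed."]),
        ("Reviewed by J. Smith in person.", ["Reviewed by J. Smith in person."]),
    ],
)
def test_sentence_splitting(text, expected):
    assert [t for t, _, _ in split_sentences(text)] == expected


def test_entities_worked_example():
    spans = annotate_entities("17 women participated")
    assert [(e.kind, e.span) for e in spans] == [("integer", (0, 2)), ("person", (3, 8))]
    assert spans[0].normalized_value == 17


def test_entities_dates_normalized():
    text = "between March 2004 and May 2006"
    dates = [e for e in annotate_entities(text) if e.kind == "date"]
    assert [e.normalized_value[:2] for e in dates] == [(2004, 3), (2006, 5)]


def test_entities_measurements_win_over_parts():
    text = "received 3.6 mg every 28 days"
    spans = annotate_entities(text)
    kinds = [(e.kind, text[e.start:e.end]) for e in spans]
    assert ("measurement", "3.6 mg") in kinds
    assert ("measurement", "28 days") in kinds
    assert all(k != "integer" for k, _ in kinds)


def test_entity_spans_disjoint_on_corpus(small_corpus):
    _, ann, _ = small_corpus
    for a in ann:
        for s in a.sentences:
            spans = sorted(e.span for e in s.entities)
            for (a1, b1), (a2, _) in zip(spans, spans[1:]):
                assert a2 >= b1


def test_sentences_ordered_and_disjoint(small_corpus):
    _, ann, _ = small_corpus
    for a in ann:
        spans = [s.doc_span for s in a.sentences]
        assert spans == sorted(spans)
        for (a1, b1), (a2, _) in zip(spans, spans[1:]):
            assert a2 >= b1
        assert [s.index for s in a.sentences] == list(range(len(a.sentences)))


def test_section_paths_on_synthetic_article(small_corpus):
    _, ann, _ = small_corpus
    a = ann[0]
    paths = {s.text: s.section_path for s in a.sentences}
    assert any(p == ("Methods", "Patients") for p in paths.values())
    assert any(p == ("Abstract",) for p in paths.values())


def test_preprocess_deterministic(small_corpus):
    docs, ann, _ = small_corpus
    again = preprocess_document(docs[0])
    assert [s.text for s in again.sentences] == [s.text for s in ann[0].sentences]
    assert [s.entities for s in again.sentences] == [s.entities for s in ann[0].sentences]


def test_idempotent_on_plain_text_rendering(small_corpus):
    """Re-splitting the normalized sentence stream reproduces itself."""
    _, ann, _ = small_corpus
    for a in ann[:2]:
        body = [
            s
            for s in a.sentences
            if not s.is_heading and s.text[-1] in ".!?"
        ]
        text = " ".join(s.text for s in body)
        resplit = [t for t, _, _ in split_sentences(text)]
        assert resplit == [s.text for s in body]
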