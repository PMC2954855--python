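"""Corpus I/O: article files, gold annotations, extraction results, citations.

Articles arrive as journal HTML, XML with ``<sec><title>`` section markup, or
plain text; the format is auto-detected from the content unless a hint is
given.  Gold annotations and extraction results are stored as JSON: per
document, per element, a list of answers, each naming a 0-based sentence
index and a list of 0-based half-open character intervals relative to the
sentence text.  Publication details (first author, year, DOI) are parsed
from a locally stored PubMed/MEDLINE-style citation record rather than
fetched over the network.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from lxml import etree

from .schema import ElementSpec, SchemaError

__all__ = [
    "RawDocument",
    "GoldAnswer",
    "GoldAnnotation",
    "CitationRecord",
    "ValidationError",
    "load_document",
    "detect_format",
    "read_gold",
    "write_gold",
    "validate_gold",
    "write_results",
    "read_results",
    "parse_citation",
]


class ValidationError(ValueError):
    """An annotation file violates a structural invariant."""


@dataclass(frozen=True)
class RawDocument:
    doc_id: str
    format: str  # html | xml | text
    content: str
    citation_path: Optional[str] = None

    def __post_init__(self):
        if not self.content:
            raise ValidationError(f"{self.doc_id}: empty document content")


@dataclass(frozen=True)
class GoldAnswer:
    sentence_index: int
    fragments: Tuple[Tuple[int, int], ...] = ()


@dataclass
class GoldAnnotation:
    doc_id: str
    answers: Dict[str, List[GoldAnswer]] = field(default_factory=dict)

    def for_element(self, element_id: str) -> List[GoldAnswer]:
        return self.answers.get(element_id, [])


@dataclass(frozen=True)
class CitationRecord:
    first_author_name: Optional[str] = None
    publication_year: Optional[int] = None
    doi: Optional[str] = None


_XML_DECL = re.compile(r"^\s*<\?xml")
_HTML_TAG = re.compile(r"<(?:!doctype|html|head|body|div|p|h[1-6]|br|table|ul|ol|b|i)\b", re.I)
_ANY_TAG = re.compile(r"<[a-zA-Z!/][^>]*>")


def detect_format(content: str) -> str:
    """html/xml/text detection: declaration or root element -> xml, markup -> html."""
    head = content[:4000]
    if _XML_DECL.match(head):
        return "xml"
    root = re.match(r"\s*<([a-zA-Z!][\w-]*)", content)
    if root is not None:
        # a leading non-HTML root element (e.g. <article>, <sec>) means XML
        return "html" if root.group(1).lower() in ("!doctype", "html") else "xml"
    if _HTML_TAG.search(head) or _ANY_TAG.search(head):
        return "html"
    return "text"


def load_document(
    path, format_hint: Optional[str] = None, citation_path: Optional[str] = None
) -> RawDocument:
    """Read an article file, normalize its encoding, and detect its format."""
    p = Path(path)
    raw = p.read_bytes()
    if not raw.strip():
        raise ValidationError(f"{p}: empty file")
    text = raw.decode("utf-8", errors="replace")
    text = unicodedata.normalize("NFC", text)
    fmt = format_hint or detect_format(text)
    if fmt not in ("html", "xml", "text"):
        raise ValidationError(f"unknown format {fmt!r}")
    return RawDocument(doc_id=p.stem, format=fmt, content=text, citation_path=citation_path)


# ---------------------------------------------------------------------------
# gold annotations


def _check_intervals(
    fragments: Sequence[Sequence[int]], where: str
) -> Tuple[Tuple[int, int], ...]:
    out: List[Tuple[int, int]] = []
    for iv in fragments:
        if len(iv) != 2 or not all(isinstance(x, int) for x in iv):
            raise ValidationError(f"{where}: malformed interval {iv!r}")
        a, b = iv
        if a < 0 or b <= a:
            raise ValidationError(f"{where}: invalid interval [{a}, {b})")
        out.append((a, b))
    out.sort()
    for (a1, b1), (a2, _) in zip(out, out[1:]):
        if a2 < b1:
            raise ValidationError(f"{where}: overlapping intervals")
    return tuple(out)


def _gold_from_payload(payload: dict, specs: Sequence[ElementSpec]) -> GoldAnnotation:
    known = {s.element_id: s for s in specs}
    doc_id = payload.get("doc_id", "")
    elements = payload.get("elements", {})
    answers: Dict[str, List[GoldAnswer]] = {}
    for eid, items in elements.items():
        if eid not in known:
            raise SchemaError(f"{doc_id}: unknown element id {eid!r}")
        spec = known[eid]
        parsed: List[GoldAnswer] = []
        for item in items:
            idx = item.get("sentence_index")
            if not isinstance(idx, int) or idx < 0:
                raise ValidationError(
                    f"{doc_id}/{eid}: bad sentence index {idx!r}"
                )
            frags = _check_intervals(
                item.get("fragments", []), f"{doc_id}/{eid}/sentence {idx}"
            )
            if spec.extraction_mode == "whole_sentence" and frags:
                raise ValidationError(
                    f"{doc_id}/{eid}: whole-sentence element must not carry fragments"
                )
            parsed.append(GoldAnswer(sentence_index=idx, fragments=frags))
        answers[eid] = parsed
    return GoldAnnotation(doc_id=doc_id, answers=answers)


def read_gold(path, specs: Sequence[ElementSpec]) -> GoldAnnotation:
    """Load and validate a gold-annotation JSON file against the schema."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return _gold_from_payload(payload, specs)


def gold_to_payload(gold: GoldAnnotation) -> dict:
    return {
        "doc_id": gold.doc_id,
        "elements": {
            eid: [
                {
                    "sentence_index": a.sentence_index,
                    "fragments": [list(iv) for iv in a.fragments],
                }
                for a in answers
            ]
            for eid, answers in sorted(gold.answers.items())
        },
    }


def write_gold(gold: GoldAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(gold_to_payload(gold), fh, indent=1, sort_keys=True)
        fh.write("\n")


def validate_gold(gold: GoldAnnotation, doc) -> None:
    """Range-check gold indices and intervals against a preprocessed document.

    ``doc`` is an :class:`~exact.preprocess.AnnotatedDocument` (duck-typed:
    needs ``sentences`` with ``text``).
    """
    n = len(doc.sentences)
    for eid, answers in gold.answers.items():
        for a in answers:
            if a.sentence_index >= n:
                raise ValidationError(
                    f"{gold.doc_id}/{eid}: sentence index {a.sentence_index} "
                    f"out of range (document has {n} sentences)"
                )
            text = doc.sentences[a.sentence_index].text
            for (s, e) in a.fragments:
                if e > len(text):
                    raise ValidationError(
                        f"{gold.doc_id}/{eid}: interval [{s}, {e}) exceeds "
                        f"sentence {a.sentence_index} bounds"
                    )


# ---------------------------------------------------------------------------
# extraction results


def write_results(results: Dict[str, "object"], path) -> None:
    """Serialize per-element extraction results to JSON (deterministic order)."""
    payload = {}
    for eid in sorted(results):
        res = results[eid]
        block: dict = {
            "candidates": [
                {
                    "sentence_index": c.sentence_index,
                    "text": c.text,
                    "base_score": c.base_score,
                    "final_score": c.final_score,
                    "fragments": [list(iv) for iv in c.fragments],
                }
                for c in res.candidates
            ]
        }
        if res.value is not None:
            block["value"] = res.value
        if res.suggestion_index is None and res.value is None:
            block["not_found"] = True
        else:
            block["suggestion_index"] = res.suggestion_index
        payload[eid] = block
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_results(path) -> Dict[str, "object"]:
    from .extract import Candidate, ElementResult

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    out: Dict[str, ElementResult] = {}
    for eid, block in payload.items():
        cands = [
            Candidate(
                sentence_index=c["sentence_index"],
                text=c["text"],
                base_score=c["base_score"],
                final_score=c["final_score"],
                fragments=tuple(tuple(iv) for iv in c["fragments"]),
            )
            for c in block.get("candidates", [])
        ]
        out[eid] = ElementResult(
            element_id=eid,
            candidates=cands,
            suggestion_index=block.get("suggestion_index"),
            value=block.get("value"),
        )
    return out


# ---------------------------------------------------------------------------
# citation records


def parse_citation(record: str) -> CitationRecord:
    """Parse first author, year and DOI from a PubMed-style citation XML."""
    try:
        root = etree.fromstring(record.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"malformed citation XML: {exc}") from exc

    author = None
    first = root.find(".//AuthorList/Author")
    if first is not None:
        last = first.findtext("LastName") or ""
        fore = first.findtext("ForeName") or first.findtext("Initials") or ""
        name = " ".join(x for x in (fore.strip(), last.strip()) if x)
        author = name or None

    year = None
    for xp in (".//PubDate/Year", ".//ArticleDate/Year", ".//DateCompleted/Year"):
        y = root.findtext(xp)
        if y and y.strip().isdigit():
            year = int(y.strip())
            break
    if year is not None and not (1900 <= year <= 2100):
        year = None

    doi = None
    for el in root.iter("ArticleId"):
        if el.get("IdType") == "doi" and el.text:
            doi = el.text.strip()
            break
    if doi is None:
        el = root.find(".//ELocationID[@EIdType='doi']")
        if el is not None and el.text:
            doi = el.text.strip()

    return CitationRecord(first_author_name=author, publication_year=year, doi=doi)
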