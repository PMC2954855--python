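"""Document pre-processing: sections, sentence splitting, entity annotation.

Turns a raw article into an ordered sentence stream suitable for sentence
classification:

1. *Section detection.*  XML articles carry explicit ``<sec><title>`` markup.
   Journal HTML does not, but headings are formatted consistently within an
   article, so the detector collects the tag signatures around cue phrases
   ("Abstract", "Methods", ...) and promotes every short text block sharing
   such a signature to a heading.  Boundaries are approximate by design.
2. *Irrelevant-section removal.*  Reference lists, related-article blocks and
   similar non-trial material are dropped.  Text occurring *after* the
   reference section is kept but flagged, because funding statements are
   sometimes placed there; classifiers for non-funding elements skip flagged
   sentences.
3. *Sentence splitting* with protection for abbreviations, decimal numbers
   and single initials; headings become one-sentence units.
4. *Entity annotation*: integers and reals (digits and spelled forms 1-20),
   units, number+unit measurements, dates (normalized year/month/day) and
   person nouns, with longest-match overlap resolution and measurements
   preferred over their parts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from lxml import etree, html as lxml_html

from .io import CitationRecord, RawDocument, ValidationError

__all__ = [
    "Section",
    "EntitySpan",
    "Sentence",
    "AnnotatedDocument",
    "detect_sections",
    "filter_sections",
    "split_sentences",
    "annotate_entities",
    "preprocess_document",
]


# --- configuration (overridable via keyword arguments) ----------------------

CUE_HEADINGS = (
    "abstract", "introduction", "background", "methods",
    "materials and methods", "results", "discussion", "conclusion",
    "conclusions", "references", "acknowledgements", "acknowledgments",
    "funding",
    # common subsection headings of trial reports
    "patients", "participants", "interventions", "outcomes",
    "statistical analysis", "study design", "procedures",
)

IRRELEVANT_HEADINGS = (
    "references", "bibliography", "literature cited", "related articles",
    "editors' notes", "editor's notes", "comments", "footnotes",
    "supplementary material", "competing interests",
)

#: headings that mark the start of the reference tail
REFERENCE_HEADINGS = ("references", "bibliography", "literature cited")

ABBREVIATIONS = (
    "e.g", "i.e", "vs", "et al", "dr", "prof", "fig", "figs", "no", "nos",
    "approx", "ca", "etc", "ref", "refs", "st", "mr", "mrs", "ms",
)

#: inline formatting tags ignored when comparing tag signatures
FORMATTING_TAGS = frozenset({"b", "i", "em", "strong", "font", "span", "a", "sup", "sub", "u"})

BLOCK_TAGS = frozenset({
    "p", "div", "h1", "h2", "h3", "h4", "h5", "h6", "li", "td", "th",
    "caption", "blockquote", "pre", "dd", "dt",
})

HEADING_MAX_TOKENS = 8

UNIT_WORDS = (
    "mg/kg", "mcg", "mg", "kg", "g", "ml", "l", "iu", "mmol", "mol",
    "units", "unit", "%", "days", "day", "weeks", "week", "months", "month",
    "years", "year", "hours", "hour", "minutes", "minute", "times",
)

PERSON_WORDS = (
    "patients", "patient", "participants", "participant", "subjects",
    "subject", "men", "man", "women", "woman", "children", "child",
    "adults", "adult", "volunteers", "volunteer", "individuals",
    "individual", "infants", "infant", "persons", "person",
)

SPELLED_NUMBERS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
    "twenty": 20,
}

MONTHS = {
    "january": 1, "february": 2, "march": 3, "april": 4, "may": 5,
    "june": 6, "july": 7, "august": 8, "september": 9, "october": 10,
    "november": 11, "december": 12, "jan": 1, "feb": 2, "mar": 3, "apr": 4,
    "jun": 6, "jul": 7, "aug": 8, "sep": 9, "sept": 9, "oct": 10,
    "nov": 11, "dec": 12,
}


# --- domain types -----------------------------------------------------------


@dataclass
class Section:
    heading_text: str
    level: int
    span: Tuple[int, int]
    parent: Optional["Section"] = None

    @property
    def path(self) -> Tuple[str, ...]:
        out = [self.heading_text]
        p = self.parent
        while p is not None:
            out.append(p.heading_text)
            p = p.parent
        return tuple(reversed(out))


@dataclass(frozen=True)
class EntitySpan:
    kind: str  # integer | real | unit | measurement | date | person
    span: Tuple[int, int]
    normalized_value: object = None

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass
class Sentence:
    index: int
    text: str
    doc_span: Tuple[int, int]
    section_path: Tuple[str, ...] = ()
    entities: Tuple[EntitySpan, ...] = ()
    post_reference_flag: bool = False
    is_heading: bool = False


@dataclass
class AnnotatedDocument:
    doc_id: str
    sentences: List[Sentence]
    sections: List[Section] = field(default_factory=list)
    citation: Optional[CitationRecord] = None


# --- internal block model ---------------------------------------------------


@dataclass
class _Block:
    text: str
    signature: Tuple[str, ...]
    is_heading: bool = False
    level: int = 0


def _norm_space(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


def _block_signature(el) -> Tuple[str, ...]:
    """Tag-name path from the element to the root, attributes stripped and
    formatting-only tags removed."""
    sig = []
    node = el
    while node is not None and isinstance(node.tag, str):
        if node.tag.lower() not in FORMATTING_TAGS:
            sig.append(node.tag.lower())
        node = node.getparent()
    return tuple(sig)


def _html_blocks(content: str) -> List[_Block]:
    try:
        root = lxml_html.fromstring(content)
    except (etree.ParserError, etree.XMLSyntaxError) as exc:
        raise ValidationError(f"unparseable HTML: {exc}") from exc
    blocks: List[_Block] = []
    for el in root.iter():
        if not isinstance(el.tag, str) or el.tag.lower() not in BLOCK_TAGS:
            continue
        # leaf blocks only: skip containers that hold further block elements
        if any(
            isinstance(d.tag, str) and d.tag.lower() in BLOCK_TAGS
            for d in el.iterdescendants()
        ):
            continue
        text = _norm_space(el.text_content())
        if not text:
            continue
        blocks.append(_Block(text=text, signature=_block_signature(el)))
    return blocks


def _mark_html_headings(blocks: List[_Block]) -> None:
    """Promote blocks sharing a tag signature with a cue-phrase block."""
    cue_signatures = {
        b.signature
        for b in blocks
        if b.text.lower().rstrip(":") in CUE_HEADINGS
        and len(b.text.split()) <= HEADING_MAX_TOKENS
    }
    heading_sigs: List[Tuple[str, ...]] = []
    for b in blocks:
        if b.signature in cue_signatures and len(b.text.split()) <= HEADING_MAX_TOKENS:
            b.is_heading = True
            if b.signature not in heading_sigs:
                heading_sigs.append(b.signature)

    # level by signature grouping: hN tags order naturally, otherwise first
    # appearance order
    def sig_rank(sig: Tuple[str, ...]) -> Tuple[int, int]:
        h = next((int(t[1]) for t in sig if re.fullmatch(r"h[1-6]", t)), 99)
        return (h, heading_sigs.index(sig))

    ordered = sorted(heading_sigs, key=sig_rank)
    levels = {sig: i + 1 for i, sig in enumerate(ordered)}
    for b in blocks:
        if b.is_heading:
            b.level = levels[b.signature]


def _xml_blocks(content: str) -> List[_Block]:
    try:
        root = etree.fromstring(content.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"unparseable XML: {exc}") from exc
    blocks: List[_Block] = []

    def walk(el, depth: int):
        for child in el:
            if not isinstance(child.tag, str):
                continue
            tag = child.tag.lower()
            if tag == "sec":
                title = child.find("title")
                if title is not None and title.text:
                    blocks.append(
                        _Block(
                            text=_norm_space("".join(title.itertext())),
                            signature=("title", "sec"),
                            is_heading=True,
                            level=depth,
                        )
                    )
                walk(child, depth + 1)
            elif tag == "title":
                continue  # handled with its <sec>
            else:
                text = _norm_space("".join(child.itertext()))
                if text:
                    blocks.append(_Block(text=text, signature=(tag,)))

    walk(root, 1)
    if not blocks:
        text = _norm_space("".join(root.itertext()))
        if text:
            blocks.append(_Block(text=text, signature=("root",)))
    return blocks


def _document_blocks(doc: RawDocument) -> List[_Block]:
    if doc.format == "xml":
        return _xml_blocks(doc.content)
    if doc.format == "html":
        blocks = _html_blocks(doc.content)
        _mark_html_headings(blocks)
        return blocks
    # plain text: paragraphs split on blank lines, single implicit section
    return [
        _Block(text=_norm_space(p), signature=("text",))
        for p in re.split(r"\n\s*\n", doc.content)
        if _norm_space(p)
    ]


# --- sections ---------------------------------------------------------------


def detect_sections(doc: RawDocument) -> List[Section]:
    """Detect section headings and nesting; plain text gets one implicit section."""
    if doc.format == "text":
        return [Section(heading_text="", level=1, span=(0, len(doc.content)))]
    blocks = _document_blocks(doc)
    sections, _ = _sections_from_blocks(blocks)
    return sections


def _sections_from_blocks(blocks: List[_Block]) -> Tuple[List[Section], List[Tuple[_Block, Tuple[int, int], Optional[Section]]]]:
    """Build Section objects plus (block, doc-span, owning section) triples.

    Document text is the blocks' texts joined by newlines; spans index it.
    """
    sections: List[Section] = []
    placed: List[Tuple[_Block, Tuple[int, int], Optional[Section]]] = []
    open_stack: List[Section] = []
    pos = 0
    for b in blocks:
        start = pos
        end = start + len(b.text)
        pos = end + 1  # newline separator
        if b.is_heading:
            while open_stack and open_stack[-1].level >= b.level:
                closed = open_stack.pop()
                closed.span = (closed.span[0], start)
            parent = open_stack[-1] if open_stack else None
            sec = Section(
                heading_text=b.text, level=b.level, span=(start, end), parent=parent
            )
            sections.append(sec)
            open_stack.append(sec)
            placed.append((b, (start, end), sec))
        else:
            placed.append((b, (start, end), open_stack[-1] if open_stack else None))
    total = pos - 1 if blocks else 0
    for sec in open_stack:
        sec.span = (sec.span[0], total)
    return sections, placed


def filter_sections(
    blocks_placed: Sequence[Tuple[_Block, Tuple[int, int], Optional[Section]]],
) -> List[Tuple[_Block, Tuple[int, int], Optional[Section], bool]]:
    """Drop blocks under irrelevant headings; flag the post-reference tail.

    Returns kept (block, span, section, post_reference_flag) tuples.
    """
    ref_start: Optional[int] = None
    for b, (start, _), sec in blocks_placed:
        if b.is_heading and b.text.lower().rstrip(":") in REFERENCE_HEADINGS:
            ref_start = start
            break
    kept = []
    for b, span, sec in blocks_placed:
        path_texts = [t.lower().rstrip(":") for t in (sec.path if sec else ())]
        if b.is_heading:
            path_texts.append(b.text.lower().rstrip(":"))
        if any(t in IRRELEVANT_HEADINGS for t in path_texts):
            continue
        post_ref = ref_start is not None and span[0] > ref_start
        kept.append((b, span, sec, post_ref))
    return kept


# --- sentence splitting -----------------------------------------------------

_BOUNDARY = re.compile(r"[.!?]+(?=\s)|[.!?]+$")


def split_sentences(text: str) -> List[Tuple[str, int, int]]:
    """Split a text region into (sentence, start, end) triples.

    Terminators end sentences except after known abbreviations, inside
    decimal numbers, and after single initials.
    """
    out: List[Tuple[str, int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        before = text[:m.start()]
        # decimal number: digit.digit has no whitespace, boundary regex
        # already requires whitespace/EOT after the period, so only guard
        # against trailing "No." style tokens below.
        last_tok = re.search(r"([A-Za-z][A-Za-z.]*)$", before)
        if last_tok:
            tok = last_tok.group(1).lower().rstrip(".")
            if tok in ABBREVIATIONS:
                continue
            if re.fullmatch(r"[A-Z]", last_tok.group(1)):
                continue  # single initial, e.g. "J. Smith"
        sent = text[start:end].strip()
        if sent:
            s0 = start + (len(text[start:end]) - len(text[start:end].lstrip()))
            out.append((sent, s0, s0 + len(sent)))
        start = end
    tail = text[start:].strip()
    if tail:
        s0 = start + (len(text[start:]) - len(text[start:].lstrip()))
        out.append((tail, s0, s0 + len(tail)))
    return out


# --- entity annotation ------------------------------------------------------

_MONTH_RX = "|".join(sorted(MONTHS, key=len, reverse=True))
_SPELLED_RX = "|".join(sorted(SPELLED_NUMBERS, key=len, reverse=True))
_UNIT_RX = "|".join(re.escape(u) for u in sorted(UNIT_WORDS, key=len, reverse=True))
_PERSON_RX = "|".join(sorted(PERSON_WORDS, key=len, reverse=True))

_RX_REAL = re.compile(r"\b\d+\.\d+\b")
_RX_INT = re.compile(r"\b\d{1,3}(?:,\d{3})+\b|\b\d+\b")
_RX_SPELLED = re.compile(rf"\b(?:{_SPELLED_RX})\b", re.I)
_RX_UNIT = re.compile(rf"(?<![\w])(?:{_UNIT_RX})(?![\w/])", re.I)
_RX_PERSON = re.compile(rf"\b(?:{_PERSON_RX})\b", re.I)
_RX_MEASUREMENT = re.compile(
    rf"\b(\d+(?:\.\d+)?|{_SPELLED_RX})\s?((?:{_UNIT_RX}))(?![\w/])", re.I
)
_RX_DATE = re.compile(
    rf"\b(?:(\d{{1,2}})\s+)?({_MONTH_RX})\.?\s+(\d{{4}})\b"      # 12 March 2004
    rf"|\b({_MONTH_RX})\.?\s+(\d{{1,2}}),\s+(\d{{4}})\b"          # March 12, 2004
    rf"|\b({_MONTH_RX})\b\.?(?:\s+(\d{{4}})\b)?"                  # March [2004]
    rf"|\b(\d{{1,2}})[/-](\d{{1,2}})[/-](\d{{4}})\b"              # 12/03/2004
    rf"|\b((?:19|20)\d{{2}})\b",                                  # bare year
    re.I,
)

_PRIORITY = {"measurement": 0, "date": 1, "real": 2, "integer": 2, "unit": 3, "person": 3}


def _date_normal(m: re.Match) -> Tuple[Optional[int], Optional[int], Optional[int]]:
    g = m.groups()
    if g[2]:  # D Month Y / Month Y
        return (int(g[2]), MONTHS[g[1].lower().rstrip(".")], int(g[0]) if g[0] else None)
    if g[5]:  # Month D, Y
        return (int(g[5]), MONTHS[g[3].lower().rstrip(".")], int(g[4]))
    if g[6]:  # Month [Y]
        return (int(g[7]) if g[7] else None, MONTHS[g[6].lower().rstrip(".")], None)
    if g[10]:  # numeric d/m/y
        return (int(g[10]), int(g[9]), int(g[8]))
    return (int(g[11]), None, None)  # bare year


def annotate_entities(text: str) -> List[EntitySpan]:
    """Annotate numbers, units, measurements, dates and person nouns."""
    cands: List[EntitySpan] = []
    for m in _RX_MEASUREMENT.finditer(text):
        num = m.group(1).lower()
        value = SPELLED_NUMBERS.get(num, None)
        if value is None:
            value = float(num) if "." in num else int(num)
        cands.append(
            EntitySpan("measurement", m.span(), (value, m.group(2).lower()))
        )
    for m in _RX_DATE.finditer(text):
        norm = _date_normal(m)
        y = norm[0]
        if y is not None and not (1900 <= y <= 2099):
            continue
        if y is None and norm[2] is None and not m.group()[0].isupper():
            continue  # bare month name must be capitalized ("may" the modal)
        cands.append(EntitySpan("date", m.span(), norm))
    for m in _RX_REAL.finditer(text):
        cands.append(EntitySpan("real", m.span(), float(m.group())))
    for m in _RX_INT.finditer(text):
        cands.append(EntitySpan("integer", m.span(), int(m.group().replace(",", ""))))
    for m in _RX_SPELLED.finditer(text):
        cands.append(EntitySpan("integer", m.span(), SPELLED_NUMBERS[m.group().lower()]))
    for m in _RX_UNIT.finditer(text):
        cands.append(EntitySpan("unit", m.span(), m.group().lower()))
    for m in _RX_PERSON.finditer(text):
        cands.append(EntitySpan("person", m.span(), m.group().lower()))

    # longest match wins; measurements beat their parts, dates beat bare numbers
    cands.sort(key=lambda e: (_PRIORITY[e.kind], -(e.end - e.start), e.start))
    chosen: List[EntitySpan] = []
    for c in cands:
        if all(c.end <= o.start or c.start >= o.end for o in chosen):
            chosen.append(c)
    chosen.sort(key=lambda e: e.start)
    return chosen


# --- composition ------------------------------------------------------------


def preprocess_document(
    doc: RawDocument, citation: Optional[CitationRecord] = None
) -> AnnotatedDocument:
    """Full pre-processing: sections -> filtering -> sentences -> entities."""
    blocks = _document_blocks(doc)
    if not blocks:
        raise ValidationError(f"{doc.doc_id}: no extractable text")
    sections, placed = _sections_from_blocks(blocks)
    kept = filter_sections(placed)

    sentences: List[Sentence] = []
    for b, (bstart, _), sec, post_ref in kept:
        if b.is_heading:
            path = sec.path if sec else ()
            pieces = [(b.text, 0, len(b.text))]
            heading = True
        else:
            path = sec.path if sec else ()
            pieces = split_sentences(b.text)
            heading = False
        for text, s0, s1 in pieces:
            sentences.append(
                Sentence(
                    index=len(sentences),
                    text=text,
                    doc_span=(bstart + s0, bstart + s1),
                    section_path=path,
                    entities=tuple(annotate_entities(text)),
                    post_reference_flag=post_ref,
                    is_heading=heading,
                )
            )
    return AnnotatedDocument(
        doc_id=doc.doc_id, sentences=sentences, sections=sections, citation=citation
    )
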