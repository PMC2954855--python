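"""Fragment extraction, redundancy fallback, score boosting and the pipeline.

The second stage of the engine.  Top-ranked candidate sentences are run
through per-element *weak rules*: intentionally under-specific patterns
(regexes over text and annotated entity spans) that are accurate only inside
a pre-selected sentence — the first date for an enrolment start date, an
integer next to a person noun for the sample size, a capitalized word
sequence for a funding organization.  When no rule fires and the element is
one whose values have no strong surface structure (outcome names, the
experimental treatment name), a redundancy extractor mines phrases repeated
across the top-five sentences instead.

Candidates whose sentence matched a rule (or received redundancy fragments)
get their confidence boosted, which may re-order the top-five list.  The
top candidate becomes the *system's suggestion* if its final score clears
the not-found threshold τ; otherwise "not found" is reported.  Candidates
below τ keep no highlighted fragments.  Eligibility criteria are
whole-sentence targets and never carry fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Set, Tuple

import yaml

from .classify import Candidate, TrainedModel, rank_candidates
from .io import CitationRecord
from .preprocess import AnnotatedDocument, Sentence
from .schema import (
    CITATION_ELEMENTS,
    ElementSpec,
    MODE_CITATION,
    MODE_WHOLE_SENTENCE,
    REDUNDANCY_ELEMENTS,
    SchemaError,
)

__all__ = [
    "WeakRule",
    "ElementResult",
    "load_rules",
    "default_rules",
    "apply_weak_rules",
    "redundancy_extract",
    "boost_and_rerank",
    "run_pipeline",
]

Interval = Tuple[int, int]


@dataclass(frozen=True)
class WeakRule:
    element_id: str
    pattern: str
    take: str = "first"  # first | last | all | all_but_last
    priority: int = 0
    ignorecase: bool = False
    require_entity: Optional[str] = None
    boost_only: bool = False


@dataclass
class ElementResult:
    element_id: str
    candidates: List[Candidate] = field(default_factory=list)
    suggestion_index: Optional[int] = None  # sentence index of the suggestion
    value: Optional[str] = None  # citation-mode elements

    @property
    def not_found(self) -> bool:
        return self.suggestion_index is None and self.value is None

    @property
    def suggestion(self) -> Optional[Candidate]:
        for c in self.candidates:
            if c.sentence_index == self.suggestion_index:
                return c
        return None


# ---------------------------------------------------------------------------
# rule loading

_PLACEHOLDER = re.compile(r"\{(integer|real|person|date|measurement|unit)\}")


def _check_compiles(rule: WeakRule) -> None:
    dummy = _PLACEHOLDER.sub(lambda m: f"(?:DUMMY_{m.group(1)})", rule.pattern)
    try:
        re.compile(dummy, re.IGNORECASE if rule.ignorecase else 0)
    except re.error as exc:
        raise ValueError(f"rule for {rule.element_id} does not compile: {exc}") from exc


def load_rules(path) -> Dict[str, List[WeakRule]]:
    """Load a rules config file (YAML; one block per element)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    rules: Dict[str, List[WeakRule]] = {}
    for eid, blocks in payload.items():
        out = []
        for i, blk in enumerate(blocks):
            rule = WeakRule(
                element_id=eid,
                pattern=blk["pattern"],
                take=blk.get("take", "first"),
                priority=blk.get("priority", i),
                ignorecase=blk.get("ignorecase", False),
                require_entity=blk.get("require_entity"),
                boost_only=blk.get("boost_only", False),
            )
            if rule.take not in ("first", "last", "all", "all_but_last"):
                raise ValueError(f"{eid}: unknown take mode {rule.take!r}")
            _check_compiles(rule)
            out.append(rule)
        rules[eid] = sorted(out, key=lambda r: r.priority)
    return rules


def default_rules() -> Dict[str, List[WeakRule]]:
    """The starter rule inventory shipped with the package."""
    ref = resources.files("exact").joinpath("data/default_rules.yaml")
    with resources.as_file(ref) as p:
        return load_rules(p)


# ---------------------------------------------------------------------------
# rule application


def _compile_for_sentence(rule: WeakRule, sentence: Sentence):
    """Expand entity placeholders against this sentence's entity spans."""
    groups: Dict[str, str] = {}

    def sub(m: re.Match) -> str:
        kind = m.group(1)
        name = f"ph{len(groups)}"
        groups[name] = kind
        texts = sorted(
            {sentence.text[e.start:e.end] for e in sentence.entities if e.kind == kind},
            key=len,
            reverse=True,
        )
        if not texts:
            return f"(?P<{name}>(?!))"
        return f"(?P<{name}>" + "|".join(re.escape(t) for t in texts) + ")"

    pat = _PLACEHOLDER.sub(sub, rule.pattern)
    return re.compile(pat, re.IGNORECASE if rule.ignorecase else 0), groups


def _entity_spans(sentence: Sentence, kind: str) -> List[Interval]:
    return [e.span for e in sentence.entities if e.kind == kind]


def _match_fragments(m: re.Match, groups: Dict[str, str], sentence: Sentence) -> Optional[List[Interval]]:
    """Fragments of one match, or None if a placeholder is misaligned."""
    gd = m.groupdict()
    for name, kind in groups.items():
        if gd.get(name) is not None and m.span(name) not in _entity_spans(sentence, kind):
            return None
    frag_names = [n for n in gd if n.startswith("frag") and gd[n] is not None]
    if frag_names:
        return [m.span(n) for n in sorted(frag_names)]
    return [m.span()]


def apply_weak_rules(
    rules: Sequence[WeakRule], element_id: str, candidate: Candidate, sentence: Sentence
) -> List[Interval]:
    """Try the element's rules in priority order on one candidate sentence.

    Returns the first matching rule's fragment intervals (possibly an empty
    list when no rule matches).  ``boost_only`` rules signal a match with a
    sentinel empty-span list handled by the pipeline.
    """
    for rule in rules:
        if rule.element_id != element_id:
            continue
        rx, groups = _compile_for_sentence(rule, sentence)
        frags: List[Interval] = []
        for m in rx.finditer(sentence.text):
            mf = _match_fragments(m, groups, sentence)
            if mf is None:
                continue
            frags.extend(mf)
            if rule.take == "first":
                break
        if not frags:
            continue
        if rule.take == "last":
            frags = frags[-1:]
        elif rule.take == "all_but_last" and len(frags) >= 2:
            frags = frags[:-1]
        if rule.require_entity:
            spans = _entity_spans(sentence, rule.require_entity)
            frags = [
                f for f in frags
                if any(f[0] < e and f[1] > s for (s, e) in spans)
            ]
        frags = _dedupe(frags)
        if frags:
            if rule.boost_only:
                return [(0, 0)]  # match signal only; no highlighted fragments
            return frags
    return []


def _dedupe(frags: List[Interval]) -> List[Interval]:
    out: List[Interval] = []
    for f in sorted(set(frags)):
        if all(f[1] <= g[0] or f[0] >= g[1] for g in out):
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# redundancy extraction

_STOPWORDS = frozenset(
    """a an the of to in and or for at with by on as is are was were be been
    this that these those from into than then it its their his her our your
    we they he she you i not no nor but if while during between among per
    each both all any some most more less least very after before about
    over under out up down off again further once here there when where why
    how which who whom such own same so too can will just should now did do
    does doing have has had having""".split()
)

_BOILERPLATE_TOKENS = frozenset(
    """primary secondary outcome outcomes endpoint endpoints end point
    points measure measures was were assessed measured evaluated defined
    randomly assigned randomised randomized receive received receiving
    treatment treatments trial study patients participants subjects group
    groups arm arms main key""".split()
)

_TOKEN = re.compile(r"[\w%]+(?:[-/'][\w%]+)*")


def redundancy_extract(
    element_id: str,
    candidates: Sequence[Candidate],
    sentences: Dict[int, Sentence],
    min_sentences: int = 2,
    max_order: int = 5,
) -> List[Tuple[Candidate, List[Interval]]]:
    """Mine phrases shared by the top candidates and map them back to spans.

    Candidate n-grams (orders 1..``max_order``) occurring in at least
    ``min_sentences`` of the top-five sentences, minus stoplisted phrases,
    are ranked by length x frequency; the longest non-overlapping survivors
    become fragments in every containing sentence.
    """
    if element_id not in REDUNDANCY_ELEMENTS:
        raise SchemaError(f"redundancy extraction not permitted for {element_id}")
    tokenized: Dict[int, List[Tuple[str, Interval]]] = {}
    for c in candidates:
        sent = sentences[c.sentence_index]
        tokenized[c.sentence_index] = [
            (m.group().lower(), m.span()) for m in _TOKEN.finditer(sent.text)
        ]

    ngram_docs: Dict[Tuple[str, ...], Set[int]] = {}
    for idx, toks in tokenized.items():
        words = [t for t, _ in toks]
        seen: Set[Tuple[str, ...]] = set()
        for n in range(1, max_order + 1):
            for i in range(len(words) - n + 1):
                seen.add(tuple(words[i:i + n]))
        for g in seen:
            ngram_docs.setdefault(g, set()).add(idx)

    stop = _STOPWORDS | _BOILERPLATE_TOKENS
    shared = [
        (g, idxs)
        for g, idxs in ngram_docs.items()
        if len(idxs) >= min_sentences and not all(t in stop for t in g)
        and g[0] not in _STOPWORDS and g[-1] not in _STOPWORDS
    ]
    # length x frequency, deterministic tie-break
    shared.sort(key=lambda gi: (-len(gi[0]) * len(gi[1]), gi[0]))

    frags_by_sentence: Dict[int, List[Interval]] = {c.sentence_index: [] for c in candidates}
    for g, idxs in shared:
        n = len(g)
        for idx in idxs:
            toks = tokenized[idx]
            words = [t for t, _ in toks]
            for i in range(len(words) - n + 1):
                if tuple(words[i:i + n]) == g:
                    span = (toks[i][1][0], toks[i + n - 1][1][1])
                    accepted = frags_by_sentence[idx]
                    if all(span[1] <= a[0] or span[0] >= a[1] for a in accepted):
                        accepted.append(span)
    out = []
    for c in candidates:
        frags = sorted(frags_by_sentence[c.sentence_index])
        if frags:
            out.append((c, frags))
    return out


# ---------------------------------------------------------------------------
# boosting and the full pipeline


def boost_and_rerank(
    candidates: Sequence[Candidate], matched: Set[int], lam: float = 0.5
) -> List[Candidate]:
    """Boost matched candidates by ``base + λ(1-base)`` and re-sort.

    Bounded and monotone: base <= final <= 1; unmatched candidates are
    unchanged, so re-ranking can only swap matched past unmatched.
    """
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    boosted = [
        replace(
            c,
            final_score=(
                c.base_score + lam * (1.0 - c.base_score)
                if c.sentence_index in matched
                else c.base_score
            ),
        )
        for c in candidates
    ]
    boosted.sort(key=lambda c: (-c.final_score, c.sentence_index))
    return boosted


def run_pipeline(
    model: TrainedModel,
    rules: Dict[str, List[WeakRule]],
    doc: AnnotatedDocument,
    specs: Sequence[ElementSpec],
    tau: float = 0.5,
    lam: float = 0.5,
    k: int = 5,
    citation: Optional[CitationRecord] = None,
) -> Dict[str, ElementResult]:
    """Classify, extract, boost, re-rank and threshold every element."""
    citation = citation or doc.citation
    results: Dict[str, ElementResult] = {}
    sentences = {s.index: s for s in doc.sentences}

    for spec in specs:
        eid = spec.element_id
        if spec.extraction_mode == MODE_CITATION:
            results[eid] = _citation_result(eid, citation)
            continue
        if eid not in model.paths:
            raise SchemaError(f"no trained path for element {eid}")
        cands = rank_candidates(model, doc, eid, k=k)
        elem_rules = rules.get(eid, [])

        frag_map: Dict[int, List[Interval]] = {}
        for c in cands:
            frags = apply_weak_rules(elem_rules, eid, c, sentences[c.sentence_index])
            if frags:
                frag_map[c.sentence_index] = frags

        if not frag_map and eid in REDUNDANCY_ELEMENTS and cands:
            for c, frags in redundancy_extract(eid, cands, sentences):
                frag_map[c.sentence_index] = frags

        matched = set(frag_map)
        cands = boost_and_rerank(cands, matched, lam=lam)

        final: List[Candidate] = []
        for c in cands:
            frags: Tuple[Interval, ...] = tuple(frag_map.get(c.sentence_index, []))
            if spec.extraction_mode == MODE_WHOLE_SENTENCE or c.final_score < tau:
                frags = ()  # whole-sentence target / too low to highlight
            frags = tuple(f for f in frags if f != (0, 0))
            final.append(replace(c, fragments=frags))

        suggestion = final[0].sentence_index if final and final[0].final_score >= tau else None
        results[eid] = ElementResult(
            element_id=eid, candidates=final, suggestion_index=suggestion
        )
    return results


def _citation_result(eid: str, citation: Optional[CitationRecord]) -> ElementResult:
    value = None
    if citation is not None:
        if eid == "author_name":
            value = citation.first_author_name
        elif eid == "date_of_publication":
            value = (
                str(citation.publication_year)
                if citation.publication_year is not None
                else None
            )
        elif eid == "doi":
            value = citation.doi
    return ElementResult(element_id=eid, value=value)
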