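"""Synthetic RCT-article generator with exact gold annotations.

Real trial-report corpora cannot be redistributed, so training and
evaluation run on generated articles that reproduce the *structural*
properties the extraction method depends on, not the lexical richness of
real prose: sectioned HTML with heading markup (Abstract, Introduction,
Methods with Patients/Interventions/Outcomes/Statistical analysis
subsections, Results, Discussion, References, and an optional post-reference
Funding paragraph); element sentences drawn from phrasing-template banks
filled with sampled values (drug names, doses, dates, sample sizes, outcome
phrases, funders, registration ids); redundant restatement of key facts in
the abstract; element absence at the per-element rates observed in a
50-article evaluation corpus of drug-treatment RCTs (e.g. enrolment dates in
~74% of articles, a registration id in ~62%, early stopping in ~4%);
multi-sentence eligibility criteria; and neutral distractor sentences so
classifiers must rely on cue terms rather than position.

A configurable fraction of articles phrase the outcome/intervention
sentences in ways the weak rules do not cover, exercising the
redundancy-extraction fallback.  Gold sentence indices refer to the
sentence stream produced by this package's own preprocessor, which makes
the annotations internally consistent by construction; fragment spans are
character intervals into the sentence text.  The same seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .io import GoldAnnotation, GoldAnswer, RawDocument
from .preprocess import AnnotatedDocument, preprocess_document
from .schema import CITATION_ELEMENTS

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "corrupt_fragments",
    "results_from_gold",
    "write_corpus",
]

#: per-element probability that an article describes the element, mirroring
#: the per-element answer frequencies of a 50-article drug-trial test set
DEFAULT_PRESENCE: Dict[str, float] = {
    "eligibility_criteria": 1.00,
    "sample_size": 1.00,
    "start_date_of_enrolment": 0.74,
    "end_date_of_enrolment": 0.74,
    "experimental_treatment_name": 1.00,
    "control_treatment_name": 1.00,
    "dose": 0.98,
    "frequency_of_treatment": 0.82,
    "route_of_treatment": 0.74,
    "duration_of_treatment": 0.82,
    "primary_outcome_name": 0.96,
    "primary_outcome_time_point": 0.62,
    "secondary_outcome_name": 0.86,
    "secondary_outcome_time_point": 0.52,
    "funding_organization_name": 0.80,
    "funding_number": 0.10,
    "early_stopping": 0.04,
    "trial_registration_id": 0.62,
}


@dataclass
class GeneratorConfig:
    n_articles: int = 80
    seed: int = 0
    presence: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PRESENCE))
    redundancy_rate: float = 0.3  # P(restating an element in the abstract)
    n_distractors_per_section: int = 3
    eligibility_multi_rate: float = 0.8  # P(>1 eligibility sentence)
    rule_nonconforming_rate: float = 0.15  # P(phrasing the weak rules miss)
    post_reference_funding_rate: float = 0.3

    def validate(self) -> None:
        probs = list(self.presence.values()) + [
            self.redundancy_rate,
            self.eligibility_multi_rate,
            self.rule_nonconforming_rate,
            self.post_reference_funding_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")


# --- value banks ------------------------------------------------------------

DRUGS = [
    "metformin", "lisinopril", "atorvastatin", "goserelin", "tamoxifen",
    "anastrozole", "zoledronic acid", "simvastatin", "omeprazole",
    "warfarin", "clopidogrel", "sertraline", "olanzapine", "ramipril",
    "amlodipine", "gabapentin", "naproxen", "candesartan", "alendronate",
    "raloxifene", "paroxetine", "donepezil", "rosuvastatin", "enalapril",
]

CONDITIONS = [
    "type 2 diabetes", "chronic heart failure", "major depressive disorder",
    "postmenopausal osteoporosis", "early breast cancer",
    "chronic obstructive pulmonary disease", "rheumatoid arthritis",
    "essential hypertension", "stable coronary artery disease",
    "advanced prostate cancer",
]

OUTCOMES = [
    "overall survival", "progression-free survival", "systolic blood pressure",
    "fasting plasma glucose concentration", "pain intensity",
    "exercise capacity", "bone mineral density", "forced expiratory volume",
    "serum ldl cholesterol concentration", "time to first hospital admission",
    "disease-free survival", "walking distance",
]

FUNDERS = [  # (name, preceded by "the")
    ("National Institutes of Health", True),
    ("Medical Research Council", True),
    ("Canadian Cancer Society", True),
    ("British Heart Foundation", True),
    ("Wellcome Trust", True),
    ("National Cancer Institute", True),
    ("Orion Pharma", False),
    ("Meridian Therapeutics", False),
]

DOSE_VALUES = ["2.5", "5", "10", "20", "25", "40", "50", "75", "100", "150", "3.6", "8", "12.5"]
DOSE_UNITS = ["mg", "mg", "mg", "mg", "mcg", "IU"]
FREQUENCIES = [
    "once daily", "twice daily", "three times daily", "every 12 hours",
    "every 28 days", "once a week",
]
ROUTES = ["orally", "intravenously", "subcutaneously", "intramuscularly"]
DURATIONS = ["6 weeks", "8 weeks", "16 weeks", "24 weeks", "52 weeks", "18 months"]
TIME_POINTS = ["4 weeks", "12 weeks", "6 months", "12 months", "36 weeks"]
MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
]

DISTRACTORS = [
    "Baseline characteristics were similar between the groups.",
    "Statistical analyses were performed with standard software.",
    "The findings should be interpreted with caution.",
    "Adverse events were recorded throughout the follow-up period.",
    "Written informed consent was obtained before any procedure.",
    "The protocol was approved by the local ethics committee.",
    "Data were analysed according to the intention-to-treat principle.",
    "Missing values were handled with multiple imputation.",
    "Compliance was monitored by pill counts and interviews.",
    "The randomization sequence was computer generated.",
    "Allocation was concealed with sealed opaque envelopes.",
    "Investigators and assessors were unaware of group assignment.",
    "These results are consistent with earlier reports.",
    "Further research is needed to confirm these observations.",
    "Sensitivity analyses yielded similar conclusions.",
    "The groups were well balanced with respect to demographic variables.",
    "Laboratory assessments were carried out at a central facility.",
    "Follow-up visits took place according to the schedule.",
    "The safety profile was acceptable and consistent with prior experience.",
    "Differences were considered significant when the confidence interval excluded unity.",
    "A blinded committee adjudicated clinical events.",
    "Quality control procedures were applied at all sites.",
]


@dataclass
class _Planted:
    element_id: str
    text: str
    fragments: List[str]


class _ArticleBuilder:
    def __init__(self, rng: random.Random, cfg: GeneratorConfig):
        self.rng = rng
        self.cfg = cfg
        self.planted: List[_Planted] = []
        self.distractor_pool = DISTRACTORS[:]
        rng.shuffle(self.distractor_pool)

    def present(self, eid: str) -> bool:
        return self.rng.random() < self.cfg.presence.get(eid, 0.0)

    def distractors(self, n: Optional[int] = None) -> List[str]:
        n = self.cfg.n_distractors_per_section if n is None else n
        n = self.rng.randint(max(1, n - 1), n + 1)
        out = []
        for _ in range(n):
            if not self.distractor_pool:
                self.distractor_pool = DISTRACTORS[:]
                self.rng.shuffle(self.distractor_pool)
            out.append(self.distractor_pool.pop())
        return out

    def plant(self, text: str, *slots: Tuple[str, List[str]]) -> str:
        for eid, frags in slots:
            self.planted.append(_Planted(eid, text, list(frags)))
        return text


def _build_article(rng: random.Random, cfg: GeneratorConfig) -> Tuple[str, List[_Planted]]:
    b = _ArticleBuilder(rng, cfg)
    condition = rng.choice(CONDITIONS)

    drugs = rng.sample(DRUGS, 2)
    exp_drug = drugs[0]
    ctrl_drug = "placebo" if rng.random() < 0.5 else drugs[1]
    dose_pairs = rng.sample(DOSE_VALUES, 2)
    unit_e, unit_c = rng.choice(DOSE_UNITS), rng.choice(DOSE_UNITS)
    dose_e, dose_c = f"{dose_pairs[0]} {unit_e}", f"{dose_pairs[1]} {unit_c}"
    freq_e, freq_c = rng.sample(FREQUENCIES, 2)
    route_e = rng.choice(ROUTES)
    duration = rng.choice(DURATIONS)
    n_size = rng.randrange(40, 900)
    m1, m2 = sorted(rng.sample(range(12), 2))
    y1 = rng.randrange(1995, 2008)
    y2 = y1 + rng.randrange(0, 3) + (1 if m2 <= m1 else 0)
    start_date = f"{MONTH_NAMES[m1]} {y1}"
    end_date = f"{MONTH_NAMES[m2]} {y2}"
    p_outcome, s_outcome = rng.sample(OUTCOMES, 2)
    tp_p, tp_s = rng.choice(TIME_POINTS), rng.choice(TIME_POINTS)
    funder, funder_the = rng.choice(FUNDERS)
    grant = f"R01-HL{rng.randrange(100000, 999999)}"
    nct = f"NCT{rng.randrange(10 ** 7, 10 ** 8)}"
    nonconforming = rng.random() < cfg.rule_nonconforming_rate

    has = {eid: b.present(eid) for eid in DEFAULT_PRESENCE}
    # parameters require an intervention sentence to live in
    has["experimental_treatment_name"] = True
    has["control_treatment_name"] = True

    abstract: List[str] = []
    patients: List[str] = []
    interventions: List[str] = []
    outcomes_sec: List[str] = []
    results_sec: List[str] = []
    discussion: List[str] = []

    # --- eligibility ---------------------------------------------------
    age1 = rng.randrange(18, 55)
    age2 = age1 + rng.randrange(10, 40)
    elig = [
        b.plant(
            f"Patients were eligible if they had {condition} and were aged "
            f"{age1} to {age2} years.",
            ("eligibility_criteria", []),
        )
    ]
    if rng.random() < cfg.eligibility_multi_rate:
        elig.append(
            b.plant(
                "Exclusion criteria included pregnancy, severe renal "
                "impairment, and known hypersensitivity to the study drugs.",
                ("eligibility_criteria", []),
            )
        )
        if rng.random() < 0.5:
            elig.append(
                b.plant(
                    f"Eligible participants had documented {condition} for at "
                    "least six months before screening.",
                    ("eligibility_criteria", []),
                )
            )
    patients.extend(elig)

    # --- enrolment dates -------------------------------------------------
    if has["start_date_of_enrolment"] or has["end_date_of_enrolment"]:
        slots = []
        if has["start_date_of_enrolment"]:
            slots.append(("start_date_of_enrolment", [start_date]))
        if has["end_date_of_enrolment"]:
            slots.append(("end_date_of_enrolment", [end_date]))
        if has["start_date_of_enrolment"] and has["end_date_of_enrolment"]:
            text = rng.choice([
                f"Patients were recruited between {start_date} and {end_date}.",
                f"Enrolment began in {start_date} and ended in {end_date}.",
            ])
        elif has["start_date_of_enrolment"]:
            text = f"Enrolment started in {start_date}."
        else:
            text = f"The last participant was enrolled in {end_date}."
        patients.append(b.plant(text, *slots))

    # --- sample size ----------------------------------------------------
    size_frag = None
    if has["sample_size"]:
        person = rng.choice(["patients", "participants", "subjects"])
        size_frag = f"{n_size} {person}"
        results_sec.append(
            b.plant(
                f"A total of {size_frag} were enrolled and underwent "
                "randomization.",
                ("sample_size", [size_frag]),
            )
        )
        if rng.random() < cfg.redundancy_rate:
            abstract.append(
                b.plant(
                    f"In total, {size_frag} with {condition} were randomly "
                    "assigned in this trial.",
                    ("sample_size", [size_frag]),
                )
            )

    # --- interventions ---------------------------------------------------
    param_e = []
    if has["dose"]:
        param_e.append(dose_e)
    if has["route_of_treatment"]:
        param_e.append(route_e)
    if has["frequency_of_treatment"]:
        param_e.append(freq_e)
    detail_e = f" ({' '.join(param_e)})" if param_e else ""
    param_c = []
    if has["dose"]:
        param_c.append(dose_c)
    if has["frequency_of_treatment"]:
        param_c.append(freq_c)
    detail_c = f" ({' '.join(param_c)})" if param_c else ""
    tail = f" for {duration}" if has["duration_of_treatment"] else ""

    slots = [
        ("experimental_treatment_name", [exp_drug]),
        ("control_treatment_name", [ctrl_drug]),
    ]
    if has["dose"]:
        slots.append(("dose", [dose_e, dose_c]))
    if has["frequency_of_treatment"]:
        frags = [freq_e, freq_c] if has["dose"] else [freq_e]
        slots.append(("frequency_of_treatment", frags))
    if has["route_of_treatment"]:
        slots.append(("route_of_treatment", [route_e]))
    if has["duration_of_treatment"]:
        slots.append(("duration_of_treatment", [duration]))

    if nonconforming:
        text = (
            f"Treatment consisted of {exp_drug}{detail_e} compared with "
            f"{ctrl_drug}{detail_c}{tail}."
        )
    else:
        lead = rng.choice([
            "Patients were randomly assigned to receive",
            "Participants received either",
        ])
        text = f"{lead} {exp_drug}{detail_e} or {ctrl_drug}{detail_c}{tail}."
    interventions.append(b.plant(text, *slots))

    if rng.random() < cfg.redundancy_rate:
        abstract.append(
            b.plant(
                f"Patients with {condition} received {exp_drug} or "
                f"{ctrl_drug} in a double-blind design.",
                ("experimental_treatment_name", [exp_drug]),
                ("control_treatment_name", [ctrl_drug]),
            )
        )

    # --- outcomes ---------------------------------------------------------
    if has["primary_outcome_name"]:
        tp_part = has["primary_outcome_time_point"]
        if nonconforming:
            text = f"Efficacy was evaluated using {p_outcome} in all randomized participants."
            slots = [("primary_outcome_name", [p_outcome])]
            outcomes_sec.append(b.plant(text, *slots))
            abstract.append(
                b.plant(
                    f"Treatment effects on {p_outcome} were examined during follow-up.",
                    ("primary_outcome_name", [p_outcome]),
                )
            )
            if tp_part:
                outcomes_sec.append(
                    b.plant(
                        f"Assessments of the principal measure were performed at {tp_p}.",
                        ("primary_outcome_time_point", [tp_p]),
                    )
                )
        else:
            if tp_part:
                text = f"The primary outcome was {p_outcome}, assessed at {tp_p}."
                slots = [
                    ("primary_outcome_name", [p_outcome]),
                    ("primary_outcome_time_point", [tp_p]),
                ]
            else:
                text = f"The primary outcome was {p_outcome}."
                slots = [("primary_outcome_name", [p_outcome])]
            outcomes_sec.append(b.plant(text, *slots))
            if rng.random() < cfg.redundancy_rate:
                abstract.append(
                    b.plant(
                        f"The primary outcome was {p_outcome}.",
                        ("primary_outcome_name", [p_outcome]),
                    )
                )
    if has["secondary_outcome_name"]:
        if has["secondary_outcome_time_point"]:
            text = f"Secondary outcomes included {s_outcome}, measured at {tp_s}."
            slots = [
                ("secondary_outcome_name", [s_outcome]),
                ("secondary_outcome_time_point", [tp_s]),
            ]
        else:
            text = f"The secondary outcome was {s_outcome}."
            slots = [("secondary_outcome_name", [s_outcome])]
        outcomes_sec.append(b.plant(text, *slots))

    # --- registration and early stopping ---------------------------------
    if has["trial_registration_id"]:
        abstract.append(
            b.plant(
                f"This trial is registered with ClinicalTrials.gov, number {nct}.",
                ("trial_registration_id", [nct]),
            )
        )
    if has["early_stopping"]:
        frag = "stopped early"
        results_sec.append(
            b.plant(
                f"The trial was {frag} on the recommendation of the data "
                "monitoring committee.",
                ("early_stopping", [frag]),
            )
        )

    # --- funding ----------------------------------------------------------
    funding_sentences: List[str] = []
    if has["funding_organization_name"]:
        the = "the " if funder_the else ""
        if has["funding_number"]:
            text = f"This work was supported by grant {grant} from {the}{funder}."
            funding_sentences.append(
                b.plant(
                    text,
                    ("funding_organization_name", [funder]),
                    ("funding_number", [grant]),
                )
            )
        else:
            verb = rng.choice(["funded", "supported"])
            funding_sentences.append(
                b.plant(
                    f"This study was {verb} by {the}{funder}.",
                    ("funding_organization_name", [funder]),
                )
            )

    # --- assemble HTML -----------------------------------------------------
    abstract = b.distractors(1) + abstract + b.distractors(1)
    title = (
        f"A randomized controlled trial of two treatment strategies in "
        f"patients with {condition}"
    )
    post_ref_funding = (
        funding_sentences and rng.random() < cfg.post_reference_funding_rate
    )

    def para(sentences: Sequence[str]) -> str:
        return "<p>" + " ".join(sentences) + "</p>"

    parts = [
        "<html><head><title>%s</title></head><body>" % title,
        f"<h1>{title}</h1>",
        "<h2>Abstract</h2>",
        para(abstract),
        "<h2>Introduction</h2>",
        para(b.distractors()),
        "<h2>Methods</h2>",
        "<h3>Patients</h3>",
        para(patients + b.distractors(1)),
        "<h3>Interventions</h3>",
        para(interventions + b.distractors(1)),
        "<h3>Outcomes</h3>",
        para(outcomes_sec + b.distractors(1)),
        "<h3>Statistical analysis</h3>",
        para(b.distractors(2)),
        "<h2>Results</h2>",
        para(results_sec + b.distractors()),
        "<h2>Discussion</h2>",
        para(b.distractors()),
    ]
    if funding_sentences and not post_ref_funding:
        parts.append(para(funding_sentences))
    parts.append("<h2>References</h2>")
    n_refs = rng.randrange(3, 6)
    for i in range(n_refs):
        year = rng.randrange(1990, 2009)
        parts.append(
            f"<p>{i + 1}. Author {chr(65 + i)}, et al. Prior work on "
            f"{rng.choice(CONDITIONS)}. J Clin Res. {year}.</p>"
        )
    if post_ref_funding:
        parts.append("<h2>Funding</h2>")
        parts.append(para(funding_sentences))
    parts.append("</body></html>")
    return "\n".join(parts), b.planted


def _gold_from_planted(
    doc: AnnotatedDocument, planted: Sequence[_Planted]
) -> GoldAnnotation:
    # queue of sentence indices per exact sentence text, in document order
    index_queues: Dict[str, List[int]] = {}
    for s in doc.sentences:
        index_queues.setdefault(s.text, []).append(s.index)
    taken: Dict[Tuple[str, str], int] = {}  # (element, text) -> uses
    answers: Dict[str, List[GoldAnswer]] = {}

    for p in planted:
        queue = index_queues.get(p.text)
        if not queue:
            raise RuntimeError(
                f"planted sentence not recovered by preprocessing: {p.text!r}"
            )
        use = taken.get((p.element_id, p.text), 0)
        idx = queue[min(use, len(queue) - 1)]
        taken[(p.element_id, p.text)] = use + 1
        text = doc.sentences[idx].text
        frags: List[Tuple[int, int]] = []
        cursor = 0
        for f in p.fragments:
            at = text.find(f, cursor)
            if at < 0:
                at = text.find(f)
            if at < 0:
                raise RuntimeError(f"fragment {f!r} not found in {text!r}")
            frags.append((at, at + len(f)))
            cursor = at + len(f)
        answers.setdefault(p.element_id, []).append(
            GoldAnswer(sentence_index=idx, fragments=tuple(sorted(frags)))
        )
    for eid in answers:
        answers[eid].sort(key=lambda a: a.sentence_index)
    return GoldAnnotation(doc_id=doc.doc_id, answers=answers)


def generate_corpus(
    config: GeneratorConfig,
) -> Tuple[List[RawDocument], List[GoldAnnotation]]:
    """Generate sectioned HTML articles plus internally consistent gold."""
    config.validate()
    master = random.Random(config.seed)
    docs: List[RawDocument] = []
    golds: List[GoldAnnotation] = []
    for i in range(config.n_articles):
        rng = random.Random(master.randrange(2 ** 31))
        html, planted = _build_article(rng, config)
        doc = RawDocument(doc_id=f"synth{i:04d}", format="html", content=html)
        annotated = preprocess_document(doc)
        gold = _gold_from_planted(annotated, planted)
        docs.append(doc)
        golds.append(gold)
    return docs, golds


# ---------------------------------------------------------------------------
# controlled gold perturbation (for partial-match metric testing)


def corrupt_fragments(
    gold: Sequence[GoldAnnotation],
    rate: float,
    seed: int,
    docs: Dict[str, AnnotatedDocument],
) -> List[GoldAnnotation]:
    """Extend or truncate a ``rate`` fraction of fragment boundaries by 1-3
    tokens, producing controlled partial matches."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = random.Random(seed)
    out: List[GoldAnnotation] = []
    for g in gold:
        doc = docs[g.doc_id]
        new_answers: Dict[str, List[GoldAnswer]] = {}
        for eid, answers in g.answers.items():
            new_list = []
            for a in answers:
                text = doc.sentences[a.sentence_index].text
                frags = []
                for f in a.fragments:
                    if rng.random() < rate:
                        frags.append(_perturb(f, text, rng))
                    else:
                        frags.append(f)
                new_list.append(
                    GoldAnswer(sentence_index=a.sentence_index, fragments=tuple(frags))
                )
            new_answers[eid] = new_list
        out.append(GoldAnnotation(doc_id=g.doc_id, answers=new_answers))
    return out


def _perturb(frag: Tuple[int, int], text: str, rng: random.Random) -> Tuple[int, int]:
    import re as _re

    tokens = [m.span() for m in _re.finditer(r"\w+", text)]
    s, e = frag
    inside = [t for t in tokens if t[0] >= s and t[1] <= e]
    after = [t for t in tokens if t[0] >= e]
    before = [t for t in tokens if t[1] <= s]
    n = rng.randint(1, 3)
    extend = rng.random() < 0.5
    if extend and after:
        return (s, after[min(n, len(after)) - 1][1])
    if extend and before:
        return (before[max(0, len(before) - n)][0], e)
    if len(inside) > 1:
        keep = inside[: max(1, len(inside) - n)]
        return (s, keep[-1][1])
    if after:  # cannot truncate a one-token fragment; extend instead
        return (s, after[min(n, len(after)) - 1][1])
    if before:
        return (before[max(0, len(before) - n)][0], e)
    return frag


# ---------------------------------------------------------------------------
# helpers for closing the loop in tests and calibration checks


def results_from_gold(
    doc: AnnotatedDocument, gold: GoldAnnotation, specs
) -> Dict[str, "object"]:
    """Oracle results whose candidates are exactly the gold sentences.

    Used to calibrate the evaluation metrics themselves (a perfect system
    scores 1.0; gold corrupted at rate r scores ~1-r exact precision).
    """
    from .extract import ElementResult
    from .classify import Candidate

    out: Dict[str, ElementResult] = {}
    for spec in specs:
        eid = spec.element_id
        if eid in CITATION_ELEMENTS:
            out[eid] = ElementResult(element_id=eid)
            continue
        answers = gold.for_element(eid)
        cands = [
            Candidate(
                sentence_index=a.sentence_index,
                text=doc.sentences[a.sentence_index].text,
                base_score=1.0,
                final_score=1.0,
                fragments=tuple(a.fragments),
            )
            for a in answers[:5]
        ]
        out[eid] = ElementResult(
            element_id=eid,
            candidates=cands,
            suggestion_index=cands[0].sentence_index if cands else None,
        )
    return out


def write_corpus(docs, golds, out_dir, config: Optional[GeneratorConfig] = None) -> None:
    """Write articles (.html) and gold (.json) files plus the config used."""
    import json

    from .io import gold_to_payload

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc, gold in zip(docs, golds):
        (out / f"{doc.doc_id}.html").write_text(doc.content, encoding="utf-8")
        (out / f"{doc.doc_id}.gold.json").write_text(
            json.dumps(gold_to_payload(gold), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    if config is not None:
        payload = {
            "n_articles": config.n_articles,
            "seed": config.seed,
            "presence": config.presence,
            "redundancy_rate": config.redundancy_rate,
            "n_distractors_per_section": config.n_distractors_per_section,
            "eligibility_multi_rate": config.eligibility_multi_rate,
            "rule_nonconforming_rate": config.rule_nonconforming_rate,
            "post_reference_funding_rate": config.post_reference_funding_rate,
        }
        (out / "generator_config.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
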