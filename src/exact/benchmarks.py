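"""Published element-level benchmark figures for aggregation checks.

A published evaluation of this two-stage extraction approach on 50
previously unseen drug-trial articles reported per-element sentence- and
fragment-level performance plus overall solution-quality proportions.  The
per-element rows are reproduced here as input data: feeding them through
:func:`exact.evaluate.aggregate_rates` must reproduce the reported
macro-average rows and the sentence-count-weighted micro recalls, which
pins down the package's averaging conventions against an external
reference.
"""

from __future__ import annotations

from typing import Dict, List

#: element order used by the published tables
ELEMENT_ORDER: List[str] = [
    "eligibility_criteria",
    "sample_size",
    "start_date_of_enrolment",
    "end_date_of_enrolment",
    "experimental_treatment_name",
    "control_treatment_name",
    "dose",
    "frequency_of_treatment",
    "route_of_treatment",
    "duration_of_treatment",
    "primary_outcome_name",
    "primary_outcome_time_point",
    "secondary_outcome_name",
    "secondary_outcome_time_point",
    "funding_organization_name",
    "funding_number",
    "early_stopping",
    "trial_registration_id",
    "author_name",
    "date_of_publication",
    "doi",
]

#: sentence-level rows: articles with answers, suggestion P, suggestion R,
#: top-5 at-least-one recall, gold sentences, top-5 all-answers recall
SENTENCE_LEVEL: Dict[str, tuple] = {
    "eligibility_criteria":         (50, 0.78, 0.78, 0.98, 133, 0.77),
    "sample_size":                  (50, 0.77, 0.68, 0.84, 52, 0.83),
    "start_date_of_enrolment":      (37, 0.97, 0.86, 0.86, 37, 0.86),
    "end_date_of_enrolment":        (37, 0.91, 0.81, 0.89, 37, 0.89),
    "experimental_treatment_name":  (50, 0.86, 0.86, 0.98, 56, 0.95),
    "control_treatment_name":       (50, 0.86, 0.86, 1.00, 54, 0.96),
    "dose":                         (49, 0.81, 0.78, 0.98, 72, 0.90),
    "frequency_of_treatment":       (41, 0.80, 0.78, 1.00, 55, 0.95),
    "route_of_treatment":           (37, 0.86, 0.81, 0.95, 39, 0.95),
    "duration_of_treatment":        (41, 0.74, 0.76, 0.93, 44, 0.91),
    "primary_outcome_name":         (48, 0.66, 0.69, 0.88, 52, 0.81),
    "primary_outcome_time_point":   (31, 0.53, 0.61, 0.81, 33, 0.76),
    "secondary_outcome_name":       (43, 0.69, 0.79, 0.98, 49, 0.88),
    "secondary_outcome_time_point": (26, 0.69, 0.69, 0.88, 29, 0.83),
    "funding_organization_name":    (40, 0.47, 0.50, 0.72, 42, 0.74),
    "funding_number":               (5, 0.31, 0.80, 0.80, 5, 0.80),
    "early_stopping":               (2, 0.33, 1.00, 1.00, 2, 1.00),
    "trial_registration_id":        (31, 1.00, 0.94, 0.94, 31, 0.94),
    "author_name":                  (50, 0.98, 0.98, 0.98, 50, 0.98),
    "date_of_publication":          (50, 0.98, 0.98, 0.98, 50, 0.98),
    "doi":                          (48, 1.00, 0.98, 0.98, 48, 0.98),
}

#: fragment-level rows: gold fragments, exact P, exact R, partial P, partial R
FRAGMENT_LEVEL: Dict[str, tuple] = {
    "eligibility_criteria":         (103, 1.00, 1.00, 1.00, 1.00),
    "sample_size":                  (46, 0.89, 0.87, 0.89, 0.87),
    "start_date_of_enrolment":      (32, 1.00, 1.00, 1.00, 1.00),
    "end_date_of_enrolment":        (31, 1.00, 1.00, 1.00, 1.00),
    "experimental_treatment_name":  (54, 0.72, 0.54, 0.97, 0.72),
    "control_treatment_name":       (55, 0.83, 0.80, 0.89, 0.85),
    "dose":                         (103, 0.91, 0.90, 0.96, 0.97),
    "frequency_of_treatment":       (70, 0.91, 0.87, 0.99, 0.93),
    "route_of_treatment":           (53, 0.94, 0.92, 0.94, 0.92),
    "duration_of_treatment":        (45, 0.84, 0.91, 0.86, 0.93),
    "primary_outcome_name":         (38, 0.97, 0.97, 0.97, 0.97),
    "primary_outcome_time_point":   (33, 0.90, 0.79, 0.97, 0.85),
    "secondary_outcome_name":       (43, 0.93, 0.88, 1.00, 1.00),
    "secondary_outcome_time_point": (25, 0.72, 0.72, 0.92, 0.92),
    "funding_organization_name":    (45, 0.90, 0.98, 0.90, 0.98),
    "funding_number":               (7, 1.00, 1.00, 1.00, 1.00),
    "early_stopping":               (2, 1.00, 1.00, 1.00, 1.00),
    "trial_registration_id":        (29, 1.00, 1.00, 1.00, 1.00),
    "author_name":                  (49, 1.00, 1.00, 1.00, 1.00),
    "date_of_publication":          (49, 1.00, 1.00, 1.00, 1.00),
    "doi":                          (47, 1.00, 1.00, 1.00, 1.00),
}

#: whole-system rows: fully correct, partially correct (total), incorrect
SOLUTION_CATEGORIES: Dict[str, tuple] = {
    "eligibility_criteria":         (0.08, 0.90, 0.02),
    "sample_size":                  (0.56, 0.28, 0.16),
    "start_date_of_enrolment":      (0.88, 0.02, 0.10),
    "end_date_of_enrolment":        (0.82, 0.10, 0.08),
    "experimental_treatment_name":  (0.38, 0.60, 0.02),
    "control_treatment_name":       (0.62, 0.38, 0.00),
    "dose":                         (0.50, 0.48, 0.02),
    "frequency_of_treatment":       (0.60, 0.40, 0.00),
    "route_of_treatment":           (0.74, 0.22, 0.04),
    "duration_of_treatment":        (0.58, 0.36, 0.06),
    "primary_outcome_name":         (0.58, 0.30, 0.12),
    "primary_outcome_time_point":   (0.42, 0.46, 0.12),
    "secondary_outcome_name":       (0.60, 0.38, 0.02),
    "secondary_outcome_time_point": (0.56, 0.38, 0.06),
    "funding_organization_name":    (0.38, 0.40, 0.22),
    "funding_number":               (0.80, 0.18, 0.02),
    "early_stopping":               (0.92, 0.08, 0.00),
    "trial_registration_id":        (0.96, 0.00, 0.04),
    "author_name":                  (0.98, 0.00, 0.02),
    "date_of_publication":          (0.98, 0.00, 0.02),
    "doi":                          (0.98, 0.00, 0.02),
}


def benchmark_aggregates() -> Dict[str, float]:
    """Recompute the reported macro/micro aggregate rows from the
    per-element benchmark values."""
    from .evaluate import aggregate_rates

    order = ELEMENT_ORDER
    n_articles = [SENTENCE_LEVEL[e][0] for e in order]
    sugg_p = [SENTENCE_LEVEL[e][1] for e in order]
    sugg_r = [SENTENCE_LEVEL[e][2] for e in order]
    top5 = [SENTENCE_LEVEL[e][3] for e in order]
    n_sent = [SENTENCE_LEVEL[e][4] for e in order]
    all_r = [SENTENCE_LEVEL[e][5] for e in order]
    fe_p = [FRAGMENT_LEVEL[e][1] for e in order]
    fe_r = [FRAGMENT_LEVEL[e][2] for e in order]
    fp_p = [FRAGMENT_LEVEL[e][3] for e in order]
    fp_r = [FRAGMENT_LEVEL[e][4] for e in order]
    fully = [SOLUTION_CATEGORIES[e][0] for e in order]

    return {
        "suggestion_macro_precision": aggregate_rates(sugg_p)["macro"],
        "suggestion_macro_recall": aggregate_rates(sugg_r)["macro"],
        "top5_macro_recall": aggregate_rates(top5)["macro"],
        "top5_micro_recall": aggregate_rates(top5, n_articles)["micro"],
        "all_answers_macro_recall": aggregate_rates(all_r)["macro"],
        "all_answers_micro_recall": aggregate_rates(all_r, n_sent)["micro"],
        "fragment_exact_macro_precision": aggregate_rates(fe_p)["macro"],
        "fragment_exact_macro_recall": aggregate_rates(fe_r)["macro"],
        "fragment_partial_macro_precision": aggregate_rates(fp_p)["macro"],
        "fragment_partial_macro_recall": aggregate_rates(fp_r)["macro"],
        "fully_correct_proportion": aggregate_rates(fully)["macro"],
    }
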