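"""Information-element schema: the 21 trial characteristics and their hierarchy.

A randomized-controlled-trial report is summarised by 21 *information
elements*: eligibility criteria, sample size, enrolment dates, the
experimental/control interventions and their parameters (dose, frequency,
route, duration), primary/secondary outcomes and their time points, funding
details, early stopping, the trial registration identifier, and three
publication details (first author, year, DOI).

The 18 elements that are expressed as article sentences are organised in a
four-level tree (root -> semantic group -> subgroup -> leaf).  Sentence
classifiers are trained for every non-root node, and a leaf's confidence is
the combination of the scores along its root-to-leaf path.  The three
publication details are filled from a citation record and bypass the
classifier hierarchy entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

__all__ = [
    "ElementSpec",
    "ElementHierarchy",
    "SchemaError",
    "default_schema",
    "validate_schema",
    "ELEMENT_IDS",
    "CITATION_ELEMENTS",
    "ROOT",
]

ROOT = "root"

#: extraction modes
MODE_RULES = "rules"
MODE_REDUNDANCY = "redundancy"
MODE_WHOLE_SENTENCE = "whole_sentence"
MODE_CITATION = "citation"

#: answer cardinality
CARD_ALL = "all_distinct"
CARD_ONE = "one_of_redundant"


class SchemaError(ValueError):
    """Raised when an element schema violates a structural invariant."""


@dataclass(frozen=True)
class ElementSpec:
    """One information element: identity, extraction mode and hierarchy path."""

    element_id: str
    display_name: str
    extraction_mode: str
    cardinality: str
    hierarchy_path: Tuple[str, ...]  # root..leaf, length 4 for classifier leaves


@dataclass(frozen=True)
class ElementHierarchy:
    """Four-level tree over the 18 non-citation elements.

    ``children`` maps node-id -> ordered child node-ids; leaves are element
    ids.  ``parent`` is the inverse map (root has no entry).
    """

    children: Dict[str, Tuple[str, ...]]
    parent: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.parent:
            parent = {}
            for node, kids in self.children.items():
                for k in kids:
                    parent[k] = node
            object.__setattr__(self, "parent", parent)

    @property
    def nodes(self) -> List[str]:
        seen: List[str] = [ROOT]
        i = 0
        while i < len(seen):
            seen.extend(self.children.get(seen[i], ()))
            i += 1
        return seen

    @property
    def leaves(self) -> List[str]:
        return [n for n in self.nodes if n not in self.children]

    def path(self, leaf: str) -> Tuple[str, ...]:
        out = [leaf]
        while out[-1] in self.parent:
            out.append(self.parent[out[-1]])
        return tuple(reversed(out))


# (element_id, display name, mode, cardinality, group, subgroup)
_LEAF_TABLE = [
    ("eligibility_criteria", "Eligibility criteria", MODE_WHOLE_SENTENCE, CARD_ALL,
     "population_enrolment", "eligibility_sample"),
    ("sample_size", "Sample size", MODE_RULES, CARD_ONE,
     "population_enrolment", "eligibility_sample"),
    ("start_date_of_enrolment", "Start date of enrolment", MODE_RULES, CARD_ONE,
     "population_enrolment", "enrolment_dates"),
    ("end_date_of_enrolment", "End date of enrolment", MODE_RULES, CARD_ONE,
     "population_enrolment", "enrolment_dates"),
    ("experimental_treatment_name", "Name of experimental treatment", MODE_REDUNDANCY, CARD_ONE,
     "interventions", "treatment_identity"),
    ("control_treatment_name", "Name of control treatment", MODE_RULES, CARD_ONE,
     "interventions", "treatment_identity"),
    ("dose", "Dose", MODE_RULES, CARD_ALL,
     "interventions", "treatment_parameters"),
    ("frequency_of_treatment", "Frequency of treatment", MODE_RULES, CARD_ALL,
     "interventions", "treatment_parameters"),
    ("route_of_treatment", "Route of treatment", MODE_RULES, CARD_ALL,
     "interventions", "treatment_parameters"),
    ("duration_of_treatment", "Duration of treatment", MODE_RULES, CARD_ALL,
     "interventions", "treatment_parameters"),
    ("primary_outcome_name", "Primary outcome name", MODE_REDUNDANCY, CARD_ONE,
     "outcomes", "primary"),
    ("primary_outcome_time_point", "Primary outcome time point", MODE_RULES, CARD_ONE,
     "outcomes", "primary"),
    ("secondary_outcome_name", "Secondary outcome name", MODE_REDUNDANCY, CARD_ONE,
     "outcomes", "secondary"),
    ("secondary_outcome_time_point", "Secondary outcome time point", MODE_RULES, CARD_ONE,
     "outcomes", "secondary"),
    ("funding_organization_name", "Funding organization name", MODE_RULES, CARD_ALL,
     "funding_meta", "funding"),
    ("funding_number", "Funding number", MODE_RULES, CARD_ALL,
     "funding_meta", "funding"),
    ("early_stopping", "Early stopping", MODE_RULES, CARD_ONE,
     "funding_meta", "registration_stop"),
    ("trial_registration_id", "Registration identifier of trial", MODE_RULES, CARD_ONE,
     "funding_meta", "registration_stop"),
]

_CITATION_TABLE = [
    ("author_name", "Author name"),
    ("date_of_publication", "Date of publication"),
    ("doi", "DOI"),
]

CITATION_ELEMENTS = tuple(e for e, _ in _CITATION_TABLE)
ELEMENT_IDS = tuple(e[0] for e in _LEAF_TABLE) + CITATION_ELEMENTS

#: elements whose fragment extraction may fall back to redundancy mining
REDUNDANCY_ELEMENTS = frozenset(
    {"primary_outcome_name", "secondary_outcome_name", "experimental_treatment_name"}
)


def default_schema() -> Tuple[List[ElementSpec], ElementHierarchy]:
    """Return the built-in 21-element schema and its four-level hierarchy."""
    children: Dict[str, List[str]] = {ROOT: []}
    specs: List[ElementSpec] = []
    for eid, name, mode, card, group, subgroup in _LEAF_TABLE:
        if group not in children[ROOT]:
            children[ROOT].append(group)
            children[group] = []
        if subgroup not in children[group]:
            children[group].append(subgroup)
            children[subgroup] = []
        children[subgroup].append(eid)
        specs.append(
            ElementSpec(eid, name, mode, card, (ROOT, group, subgroup, eid))
        )
    for eid, name in _CITATION_TABLE:
        # publication details are filled from the citation record, outside the tree
        specs.append(ElementSpec(eid, name, MODE_CITATION, CARD_ONE, ()))
    hierarchy = ElementHierarchy({k: tuple(v) for k, v in children.items()})
    validate_schema(specs, hierarchy)
    return specs, hierarchy


def validate_schema(specs: List[ElementSpec], hierarchy: ElementHierarchy) -> None:
    """Assert every schema invariant; raise :class:`SchemaError` naming the violation."""
    if len(specs) != 21:
        raise SchemaError(f"expected 21 elements, got {len(specs)}")
    ids = [s.element_id for s in specs]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate element ids")

    by_id = {s.element_id: s for s in specs}
    elig = by_id.get("eligibility_criteria")
    if elig is None or elig.extraction_mode != MODE_WHOLE_SENTENCE or elig.cardinality != CARD_ALL:
        raise SchemaError("eligibility_criteria must be whole_sentence / all_distinct")
    for eid in CITATION_ELEMENTS:
        s = by_id.get(eid)
        if s is None or s.extraction_mode != MODE_CITATION:
            raise SchemaError(f"{eid} must have citation mode")
    for s in specs:
        if s.extraction_mode == MODE_REDUNDANCY and s.element_id not in REDUNDANCY_ELEMENTS:
            raise SchemaError(
                f"redundancy mode not allowed for {s.element_id}"
            )

    classifier_leaves = [s for s in specs if s.extraction_mode != MODE_CITATION]
    tree_leaves = hierarchy.leaves
    if sorted(s.element_id for s in classifier_leaves) != sorted(tree_leaves):
        raise SchemaError("hierarchy leaves do not match non-citation elements")

    seen_paths: Dict[str, Tuple[str, ...]] = {}
    for s in classifier_leaves:
        if len(s.hierarchy_path) != 4:
            raise SchemaError(f"hierarchy path of {s.element_id} has depth != 4")
        if s.hierarchy_path[0] != ROOT or s.hierarchy_path[-1] != s.element_id:
            raise SchemaError(f"malformed hierarchy path for {s.element_id}")
        if hierarchy.path(s.element_id) != s.hierarchy_path:
            raise SchemaError(f"leaf {s.element_id} in multiple paths or detached")
        seen_paths[s.element_id] = s.hierarchy_path

    # orphan check: every node reachable from root
    reachable = set(hierarchy.nodes)
    for node in hierarchy.children:
        if node not in reachable:
            raise SchemaError(f"orphan node {node}")
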